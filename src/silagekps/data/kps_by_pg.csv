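sequence_id,pg,rfcn_2015,mnc_2015,rfcn_2016,mnc_2016,rfcn_2017,mnc_2017,rfcn_151617,mnc_151617,annotation
1,1,96.2,97.7,91.8,94.7,93.8,95.5,92.2,97.3,93.5
2,1,95.4,95.4,95.2,96.1,95.8,98.8,95.1,97.7,98.7
3,1,88.0,76.4,85.7,86.5,81.3,87.2,80.7,88.9,79.9
4,1,93.7,94.8,93.0,91.1,92.5,95.7,92.1,96.1,94.3
5,2,93.9,94.8,78.8,75.2,89.2,95.8,87.8,97.3,79.1
6,2,92.8,97.7,89.9,92.6,86.3,95.7,90.8,95.7,93.8
7,2,84.8,71.5,84.2,100.0,82.5,85.8,82.7,87.7,88.8
8,2,88.0,86.1,86.4,85.6,82.2,90.6,76.0,92.6,79.1
9,3,89.6,80.7,85.1,83.5,82.4,89.3,81.8,90.4,82.3
10,3,94.6,95.2,91.2,95.7,89.9,94.1,86.1,93.8,85.7
11,3,90.4,85.9,83.2,83.1,77.9,90.3,80.5,90.0,79.3
12,3,89.1,86.3,83.6,84.5,88.5,93.0,89.8,91.8,94.5
13,3.5,90.2,80.8,83.5,88.0,81.4,89.5,81.2,91.2,83.1
14,3.5,88.6,75.5,84.0,81.6,79.7,89.0,80.3,90.2,76.6
15,3.5,91.2,93.0,89.5,92.6,91.7,93.2,92.9,94.6,92.4
16,3.5,85.6,75.9,75.4,72.5,79.5,84.7,78.4,86.1,73.7
17,3.5,91.5,89.8,86.8,91.3,86.6,91.5,86.9,92.9,86.4
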