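tooth_id,experimental_mm2,control_mm2,printed_difference_mm2,printed_ratio
1,284.31,290.7351,-6.43,0.98
2,295.56,301.2646,-5.70,0.98
3,260.19,256.4044,3.79,1.01
4,282.96,280.0253,2.93,1.01
5,297.72,289.6320,8.09,1.03
6,299.88,304.0388,-4.16,0.99
7,242.19,233.0616,9.13,1.04
8,216.63,220.1421,-3.51,0.98
9,371.16,380.7374,-9.58,0.97
10,276.84,277.0318,-0.19,1.00
11,212.58,208.5532,4.03,1.02
12,199.22,193.4995,5.72,1.03
13,337.86,346.7172,-8.86,0.97
14,278.55,277.9656,0.58,1.00
15,266.94,262.0894,4.85,1.02
16,277.47,280.2429,-2.77,0.99
17,361.71,355.3484,6.36,1.02
18,285.66,280.6460,5.01,1.02
19,232.92,233.1131,-0.19,1.00
20,277.65,278.5781,-0.93,1.00
21,313.92,312.9954,0.92,1.00
22,187.56,190.3053,-2.75,0.99
23,331.65,322.4861,9.16,1.03
24,212.67,210.7732,1.90,1.01
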