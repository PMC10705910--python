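; Relative intensities (% of base peak) of common product ions of the two
; silylated carbohydrate chromatographic peaks CB(A) and CB(B) from pear
; microplant extracts, and of the GC-EI-MS/MS standards of 4-desoxy-D-glucose
; (4DG) and 2-deoxy-D-glucose (2DG). Subscripted final digits in the printed
; values are read as additional decimals.
Name: CB_A
RT: 18.15
Derivatization: TMS
Num Peaks: 5
45 2.006
73 100.00
103 30.502
147 32.756
205 13.584

Name: CB_B
RT: 25.59
Derivatization: TMS
Num Peaks: 6
45 2.717
73 100.00
103 15.838
147 23.587
205 5.31
361 45.68

Name: 4DG
Derivatization: TMS
Num Peaks: 4
45 8.397
73 100.00
103 8.058
147 28.434

Name: 2DG
Derivatization: TMS
Num Peaks: 4
45 6.97
73 100.00
103 13.69
147 23.89
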