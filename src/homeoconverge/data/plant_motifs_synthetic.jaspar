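>SYNTF01 synthetic_plant_TF_1
A  [  19   8  76   8   8   8  76  76  76   8  76   8  76  76  19 ]
C  [  19  76   8   8   8   8   8   8   8   8   8   8   8   8  43 ]
G  [  19   8   8   8  76   8   8   8   8  76   8   8   8   8  19 ]
T  [  43   8   8  76   8  76   8   8   8   8   8  76   8   8  19 ]
>SYNTF02 synthetic_plant_TF_2
A  [  19   8   8  76   8   8   8   8   8   8  76   8   8   8  76   8  19 ]
C  [  19   8  76   8  76   8   8   8   8   8   8  76   8   8   8   8  19 ]
G  [  43   8   8   8   8  76   8   8   8   8   8   8  76  76   8   8  43 ]
T  [  19  76   8   8   8   8  76  76  76  76   8   8   8   8   8  76  19 ]
>SYNTF03 synthetic_plant_TF_3
A  [  19   8  76  76  76   8   8   8   8   8   8   8  76  76  19 ]
C  [  19   8   8   8   8   8   8   8   8   8   8  76   8   8  43 ]
G  [  43  76   8   8   8   8   8  76   8   8   8   8   8   8  19 ]
T  [  19   8   8   8   8  76  76   8  76  76  76   8   8   8  19 ]
>SYNTF04 synthetic_plant_TF_4
A  [  19  76  76   8   8   8  76  76   8  76  76   8   8   8  19 ]
C  [  43   8   8   8   8   8   8   8   8   8   8  76  76  76  43 ]
G  [  19   8   8   8  76  76   8   8   8   8   8   8   8   8  19 ]
T  [  19   8   8  76   8   8   8   8  76   8   8   8   8   8  19 ]
>SYNTF05 synthetic_plant_TF_5
A  [  19   8   8   8  76   8   8   8   8  76  76   8   8   8  43 ]
C  [  19  76  76  76   8   8   8   8  76   8   8   8   8  76  19 ]
G  [  43   8   8   8   8  76  76  76   8   8   8  76  76   8  19 ]
T  [  19   8   8   8   8   8   8   8   8   8   8   8   8   8  19 ]
>SYNTF06 synthetic_plant_TF_6
A  [  19  76   8   8   8   8   8   8  76  76   8   8   8  76   8   8  19 ]
C  [  43   8  76   8  76  76   8   8   8   8   8  76   8   8  76   8  19 ]
G  [  19   8   8   8   8   8  76   8   8   8  76   8  76   8   8  76  43 ]
T  [  19   8   8  76   8   8   8  76   8   8   8   8   8   8   8   8  19 ]
>SYNTF07 synthetic_plant_TF_7
A  [  19   8  76   8   8   8   8  76   8   8   8  76   8   8  19 ]
C  [  19  76   8   8   8  76  76   8  76  76  76   8   8   8  19 ]
G  [  43   8   8  76   8   8   8   8   8   8   8   8   8   8  19 ]
T  [  19   8   8   8  76   8   8   8   8   8   8   8  76  76  43 ]
>SYNTF08 synthetic_plant_TF_8
A  [  19   8   8   8   8  76   8   8   8   8   8   8   8   8  19 ]
C  [  19   8   8   8  76   8  76   8  76   8   8   8  76   8  43 ]
G  [  19   8  76  76   8   8   8  76   8  76  76   8   8   8  19 ]
T  [  43  76   8   8   8   8   8   8   8   8   8  76   8  76  19 ]
>SYNTF09 synthetic_plant_TF_9
A  [  19   8   8   8   8   8  76   8   8  76   8  76   8   8  43 ]
C  [  43   8   8  76  76   8   8   8   8   8  76   8  76  76  19 ]
G  [  19   8   8   8   8  76   8   8  76   8   8   8   8   8  19 ]
T  [  19  76  76   8   8   8   8  76   8   8   8   8   8   8  19 ]
>SYNTF10 synthetic_plant_TF_10
A  [  19   8   8   8   8   8   8   8   8   8   8  76   8   8  19 ]
C  [  43   8   8  76   8  76  76   8  76  76  76   8   8  76  19 ]
G  [  19  76  76   8   8   8   8  76   8   8   8   8   8   8  43 ]
T  [  19   8   8   8  76   8   8   8   8   8   8   8  76   8  19 ]
>SYNTF11 synthetic_plant_TF_11
A  [  19   8   8   8  76   8   8   8   8   8   8   8   8   8   8   8  19 ]
C  [  19   8   8   8   8   8   8   8   8   8   8   8   8   8   8   8  19 ]
G  [  43   8   8   8   8   8   8  76  76  76   8   8   8   8  76   8  43 ]
T  [  19  76  76  76   8  76  76   8   8   8  76  76  76  76   8  76  19 ]
>SYNTF12 synthetic_plant_TF_12
A  [  43  76   8   8   8   8   8   8   8  76   8   8  76   8   8  43 ]
C  [  19   8   8  76   8   8   8  76   8   8   8  76   8  76  76  19 ]
G  [  19   8  76   8   8  76   8   8  76   8   8   8   8   8   8  19 ]
T  [  19   8   8   8  76   8  76   8   8   8  76   8   8   8   8  19 ]
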