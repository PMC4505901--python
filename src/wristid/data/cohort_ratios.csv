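subject_id,group,age,sex,diagnosis,duration_years,adl,task,ratio
C1,control,46,M,,,,"step",0.03
C1,control,46,M,,,,"pursuit",1.91
C2,control,48,M,,,,"step",0.13
C2,control,48,M,,,,"pursuit",1.34
C3,control,63,M,,,,"step",0.11
C3,control,63,M,,,,"pursuit",1.28
C4,control,51,M,,,,"step",0.15
C4,control,51,M,,,,"pursuit",1.10
C5,control,54,M,,,,"step",0.14
C5,control,54,M,,,,"pursuit",1.28
C6,control,52,M,,,,"step",0.24
C6,control,52,M,,,,"pursuit",1.32
C7,control,61,F,,,,"step",0.28
C7,control,61,F,,,,"pursuit",1.58
C8,control,67,M,,,,"step",0.20
C8,control,67,M,,,,"pursuit",1.08
C9,control,68,F,,,,"step",0.17
C9,control,68,F,,,,"pursuit",1.30
C10,control,71,F,,,,"step",0.20
C10,control,71,F,,,,"pursuit",0.86
P1,patient,62,F,MSA-C,1,1,"step",0.20
P1,patient,62,F,MSA-C,1,1,"pursuit",0.75
P2,patient,77,F,SCD,4,1,"step",0.27
P2,patient,77,F,SCD,4,1,"pursuit",1.17
P3,patient,62,M,SCD,9,1,"step",0.20
P3,patient,62,M,SCD,9,1,"pursuit",0.69
P4,patient,72,M,MSA-C,3,1,"step",0.09
P4,patient,72,M,MSA-C,3,1,"pursuit",0.85
P5,patient,69,F,SCD,5,1,"step",0.22
P5,patient,69,F,SCD,5,1,"pursuit",0.57
P6,patient,65,F,MSA-C,2,1,"step",0.25
P6,patient,65,F,MSA-C,2,1,"pursuit",0.37
P7,patient,58,F,SCD,7,1,"step",0.14
P7,patient,58,F,SCD,7,1,"pursuit",0.37
P8,patient,34,F,SCD,9,1,"step",0.32
P8,patient,34,F,SCD,9,1,"pursuit",1.11
P9,patient,69,M,SCD,3,1,"step",0.16
P9,patient,69,M,SCD,3,1,"pursuit",0.20
P10,patient,70,M,SCD,10,1,"step",0.34
P10,patient,70,M,SCD,10,1,"pursuit",0.78
P11,patient,39,F,SCD,9,1,"step",0.10
P11,patient,39,F,SCD,9,1,"pursuit",0.23
P12,patient,65,F,MSA-C,2,2,"step",0.27
P12,patient,65,F,MSA-C,2,2,"pursuit",0.39
P13,patient,29,F,SCD,9,2,"step",0.27
P13,patient,29,F,SCD,9,2,"pursuit",0.50
P14,patient,76,F,SCD,5,2,"step",0.28
P14,patient,76,F,SCD,5,2,"pursuit",0.27
P15,patient,58,F,SCD,24,2,"step",0.16
P15,patient,58,F,SCD,24,2,"pursuit",0.42
P16,patient,57,M,MSA-C,4,2,"step",0.13
P16,patient,57,M,MSA-C,4,2,"pursuit",0.56
P17,patient,60,F,MSA-C,9,3,"step",0.31
P17,patient,60,F,MSA-C,9,3,"pursuit",0.35
P18,patient,71,M,MSA-C,4,3,"step",0.53
P18,patient,71,M,MSA-C,4,3,"pursuit",0.24
P19,patient,56,M,MSA-C,2,3,"step",0.27
P19,patient,56,M,MSA-C,2,3,"pursuit",0.38
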