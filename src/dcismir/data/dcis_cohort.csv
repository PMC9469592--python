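patient_id,dx_score,age,nuclear_grade,follow_up_years,treatment,recurrence
DCIS-L1,11,76,N1,10,RT and AI,NED
DCIS-L2,0,72,N1,1,NA,NED
DCIS-L3,27,74,N2,5.2,RT and AI,contra_DCIS
DCIS-L4,0,62,N3,5,TAM no RT,NED
DCIS-L5,8,<=30,N2,4.4,None,NED
DCIS-L6,27,65,N3,4,RT and TAM,NED
DCIS-L7,33,75,N2,2,None,ipsi_DCIS
DCIS-L8,28,62,N2,8,RT and AI,NED
DCIS-L9,23,68,N1,8,TAM no RT,NED
DCIS-L10,12,66,N2,NA,NA,NA
DCIS-L11,5,70,N1,NA,NA,NA
DCIS-L12,1,72,N2,8,No RT,NED
DCIS-L13,5,76,N2,4,No RT,NED
DCIS-L14,13,68,N3,7,AI no RT,NED
DCIS-L15,20,66,N2,6,AI no RT,NED
DCIS-L16,22,42,N2,NA,NA,NA
DCIS-L17,37,61,N2,6,RT and AI,NED
DCIS-L18,15,40,N2,5,NA,NED
DCIS-L19,15,65,N2,4.5,AI no RT,NED
DCIS-L20,0,72,NA,4,AI no RT,NED
DCIS-L21,0,62,N1,NA,NA,NA
DCIS-L22,24,>=80,N3,4.5,RT and TAM,NED
DCIS-L23,36,79,N3,4,None,NED
DCIS-L24,0,44,N1,10,TAM no RT,NED
DCIS-L25,6,73,N2,NA,NA,NA
DCIS-L26,28,64,N2,5,AI no RT,NED
DCIS-I1,42,78,N2,7,NA,NED
DCIS-I2,47,69,N3,8,RT and TAM,NED
DCIS-I3,52,66,N2,8,RT and AI,NED
DCIS-I4,48,59,N3,8,RT and AI,NED
DCIS-I5,39,67,N3,NA,NA,NA
DCIS-I6,40,64,N2,NA,RT and TAM,NA
DCIS-I7,39,34,N3,NA,MX,NA
DCIS-I8,47,57,N2,NA,MX,NA
DCIS-I9,40,76,N3,2,RT,ipsi_IBC
DCIS-I10,52,67,N3,4,AI,NED
DCIS-H1,56,45,N2,7.5,RT,NED
DCIS-H2,78,52,N2,8,RT and TAM,NED
DCIS-H3,64,55,N3,6,RT and AI,NED
DCIS-H4,73,72,N3,3,RT and AI,NED
DCIS-H5,55,58,N3,6,RT,NED
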