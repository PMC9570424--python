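patient_id,group,lesion_note,tm_pct,a2_pct,tma2_pct,lbc_result
CC-2,CC,stage IB3,100.0,100.0,100.0,+
CC-4,CC,stage IB2,100.0,100.0,95.6,+
CC-6,CC,stage IIB,100.0,100.0,100.0,+
CC-8,CC,stage IA1,2.5,0.0,0.0,+
CC-10,CC,stage IIA1,100.0,100.0,100.0,+
CC-11,CC,stage IIB,73.7,100.0,89.5,+
CINII-2,CINII/III,,83.3,83.3,58.3,-
CINII-4,CINII/III,,50.0,80.0,50.0,+
CINII-6,CINII/III,,78.3,91.3,78.3,+
Benign-1,benign,,0.0,0.0,0.0,-
Benign-2,benign,,0.0,0.0,0.0,-
Benign-3,benign,,8.3,8.3,8.3,-
Benign-4,benign,,4.5,0.0,0.0,-
Benign-5,benign,,0.0,0.0,0.0,-
Benign-6,benign,,0.0,0.0,0.0,-
Benign-7,benign,,45.5,0.0,0.0,-
Benign-8,benign,,73.3,40.0,40.0,-
Benign-9,benign,,0.0,0.0,0.0,-
Benign-10,benign,,0.0,0.0,0.0,-
Benign-11,benign,,36.4,9.1,9.1,-
Benign-12,benign,,0.0,0.0,0.0,-
Benign-13,benign,,0.0,11.1,0.0,-
Benign-14,benign,,20.0,20.0,20.0,-
Benign-15,benign,,54.5,9.1,0.0,-
Benign-16,benign,,0.0,0.0,0.0,-
Benign-17,benign,,36.4,45.5,36.4,-
Benign-18,benign,,58.3,0.0,0.0,+
Normal-15,normal,,0.0,0.0,0.0,-
Normal-16,normal,,0.0,0.0,0.0,-
Normal-17,normal,,0.0,0.0,0.0,-
Normal-18,normal,,0.0,0.0,0.0,-
Normal-19,normal,,50.0,0.0,15.4,+
Normal-20,normal,,0.0,23.1,0.0,+
Normal-21,normal,,36.4,0.0,0.0,+
Normal-22,normal,,0.0,0.0,0.0,+
Normal-23,normal,,0.0,0.0,0.0,-
Follow-up-1,follow-up,,10.0,0.0,0.0,-
Follow-up-2,follow-up,,0.0,0.0,0.0,-
Follow-up-3,follow-up,,10.0,0.0,0.0,-
Follow-up-4,follow-up,,13.3,13.3,13.3,-
Follow-up-5,follow-up,VINII-III,85.0,100.0,70.0,+
Follow-up-6,follow-up,,0.0,37.5,0.0,-
Follow-up-7,follow-up,VAINIII,100.0,88.0,76.0,-
Follow-up-8,follow-up,,5.0,55.0,10.0,-
Follow-up-9,follow-up,,0.0,45.0,10.0,-
Follow-up-10,follow-up,,5.0,0.0,0.0,-
Follow-up-11,follow-up,,15.0,40.0,15.0,-
Follow-up-12,follow-up,,5.0,5.0,0.0,-
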