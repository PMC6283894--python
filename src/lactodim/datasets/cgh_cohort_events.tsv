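tumor_id	sex	clinical_behavior	grade	gains	losses
T01	M	recurrence,death	2b	3p,5,8,14q,19p	11p
T02	M	recurrences,metastasis,death	2b->3	1q,3p,8q,9,14q,19p	1q,11
T03	M	recurrences,metastasis,death	2b->3	1q,5,15q,19p	11,17p
T04	F	recurrence	2b	4q	1p,11p
T05	F	recurrences,metastasis,death	2b->3	1q,8q,15q	1,4,5q,11,13q,15,16
T06	F	recurrence	2b
T07	M	persistence	2a	Y
T08	M	persistence	2a		15q,2p
T09	M	remission	1a	7,9
T10	M	remission	1a	8,Y
T11	F	remission	1a	9
T12	F	remission	1a	7p,20	13q
T13	F	remission	1a	9
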