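lesion_id,case,site,trend,clinical_response,area_change_frac,events
1a,1,dorsal,negative,positive,-0.30,transient positive increment after treatment discontinuation (month 2); regrowth month 3
2a,2,scalp,negative,positive,-0.35,
3a,3,right eye inner canthus,negative,positive,-0.30,transient positive increment after treatment discontinuation (month 1); regrowth month 2
4a,4,perianal,negative,positive,-0.30,ulceration and regrowth after treatment discontinuation (month 1)
5a,5,pectoral,null,positive,-0.30,
5b,5,lumbar,negative,positive,-0.30,
6a,6,scalp (1),negative,positive,-0.30,
6b,6,scalp (2),negative,positive,-0.30,
6c,6,left mandibular ramus,negative,positive,-0.30,
6d,6,dorsal (1),negative,positive,-0.30,
6e,6,dorsal (2),negative,positive,-0.30,
6f,6,right elbow,negative,positive,-0.30,
6g,6,left temple,negative,positive,-0.30,
7a,7,occipital,negative,positive,-0.40,
8a,8,left forearm,negative,positive,-0.30,
9a,9,vertex,negative,positive,-0.30,transient local increment during ulceration (months 5-7)
9b,9,left scapula,negative,positive,-0.35,
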