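label	point_ka	low_ka	high_ka
Western Eurasian dogs | East Asian dogs (LF)	6	6	11
Mexican wolves | Yellowstone wolves (BvH)	14	12	18
Mexican wolves | Yellowstone wolves (ZF)	14	10	17
Basenji | other dogs (AF)	32	29	34
Basenji | other dogs (ZF)	21	19	23
European wolves | East Asian wolves (AF)	33	29	38
European wolves | East Asian wolves (BvH)	27	24	30
Dogs | wolves (AF)	37	35	40
Dogs | wolves (BvH)	28	24	30
Dogs | wolves (ZF)	29	24	30
Dogs | wolves (LF)	34	17	48
North American wolves | Eurasian wolves (BvH)	31	28	32
North American wolves | Eurasian wolves (ZF)	31	29	33
Coyotes | wolves (BvH)	165	158	171
Golden Jackals | Coyote/Wolf ancestors (AF)	995	797	1038
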