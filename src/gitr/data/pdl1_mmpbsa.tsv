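component	4Z18	ISPP
Evdw	-113.96	-46.19
Eele	-456.16	-280.86
GPB	487.86	264.66
GSA	-14.65	-6.00
TdS	-73.28	-37.25
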