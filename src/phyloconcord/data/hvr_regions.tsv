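name	start	end
V1	69	99
V2	137	242
V3	433	497
V4	576	682
V5	822	879
V6	986	1043
V7	1117	1173
V8	1243	1294
V9	1435	1465
V1-V2	69	242
V3-V4	433	682
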