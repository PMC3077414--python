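id	ct_ip	ct_noab
32	29.85	38.39
33	30.76	37.01
35	30.37	39.23
36	29.49	36.46
37	29.84	37.41
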