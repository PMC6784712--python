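rating,ease_of_installation_pct,stability_pct,comfort_pct
1,0.00,0.00,0.00
2,7.14,0.00,0.00
3,7.14,0.00,0.00
4,28.57,14.29,14.29
5,57.14,85.71,85.71
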