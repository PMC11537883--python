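id	hgvs	origin	n_affected	n_families	previously_described	identified_in_current_study
NL-SV1	g.59214554_59440776dup	The Netherlands	37	1	true	false
UK-SV2	g.59378750_59391598delins[59198478_59481750inv;AGGCTGGTC]	United Kingdom	123	14	true	true
SA-SV3	g.59439317_59439318ins[AAAAAAAACTTGAAAAAGAAGTTTG59170259_59314314; 59439322_59535354inv; GGTCCAGATTGTG;59421853_59439317]	South Africa	120	6	true	true
CA-SV4	g.59202647_59406522delins[59155674_59557539inv;TAAGCA]	Canada	42	1	true	false
NL-SV5	g.59183160_59438501dup	The Netherlands	11	1	true	false
UK-SV6	g.59247345_59247346ins[A;59362745_59433393; 59218621_59433393; 59218621_59247345]	United Kingdom	25	1	true	false
UK-SV7	g.59376270_59391569delins[59182164_59633460inv;TT]	United Kingdom	2	1	true	false
UK-SV8	g.59248874_59335791delins[CT;59199986_59554298inv]	United Kingdom	12	1	true	false
DE-SV9	g.59549138_59549139ins[59336282_59545765inv;59187321_59545765]	Germany	4	1	false	true
US-SV10	g.59288296_59362561delins[59220112_59478159inv;A]	United States	16	1	false	true
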