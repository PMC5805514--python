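case_id	rule1	rule2	rule3	rule4	rule5	conclusion	restrict_rules
A02	s	s,p	p	s,p	s,p,n	s,p
A03	s	s,p	s	s,p	s,p,n	s
A04	n	n	n	n,e	n,e	n
A07	s	s,p	p	s,p	s,p,n	s,p
A08	p	s,p	p	s,p	s,p,n	p
A09	e	e	s,e	n,e	n,e	e
A10	n	n	n	n,e	-	n
A11	s	-	s	s,p	n,e	s
A12	s	s,p	p	s,p	-	s,p
A13	p	-	-	-	n,e or s,p,n	p	1,5
A14	n	n	n	n,e	-	n
A15	e	s,p	p	s,p	-	p
A16	s	s,p	s	s,p	-	s
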