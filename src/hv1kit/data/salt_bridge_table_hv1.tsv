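	WT		R205W		R208Q		R208W		G215E		G215R	
	d	a	d	a	d	a	d	a	d	a	d	a
R1-D112	✓				✓		✓		✓		✓	
R1-E119		✓				✓		✓		✓		✓
R1-D123		✓				✓		∨		✓		✓
R1-D185	∨				✓		✓		✓		✓	
R2-D112		✓	✓	∨						✓		✓
R2-E119				✓								
R2-E153											✓	
R2-D174	✓				∨				✓		✓	
R2-D185		✓		∨		✓				✓		∨
R3-D112				✓		✓		∨				
R3-D174	∨	✓	✓		✓		✓	✓	∨	✓	∨	✓
R3-E171	✓		✓		✓		✓		✓		✓	
R3-D185				✓								
H140-E119				∨	✓	∨	∨	✓	∨	∨		
H140-D185	∨	✓		∨		∨						
H168-R93										✓		
H168-E164	∨	∨			∨	∨	∨	∨	✓	∨	∨	∨
H168-E171					✓	∨				∨		
R93-E164		✓				∨		∨		∨		∨
R93-E171										✓		
R93-D174										∨		
R223-E153				✓						✓		
K131-E119	✓				∨		∨		∨		✓	
K131-D123	✓						∨		✓			
K157-E153	✓	✓	✓	∨		✓	∨	✓	✓	✓	✓	✓
K157-E171	✓	✓	∨	✓	✓	✓	✓	✓	∨	✓	∨	✓
K157-D174	∨	∨	∨	✓	∨	∨	∨	∨	∨	∨	∨	∨
G215E-R93										∨		
G215E-R211										✓		
G215E-R223										✓		
G215R-E153												∨
G215R-E171												✓
G215R-D174												✓
Sum	7✓5∨	9✓2∨	4✓2∨	6✓5∨	7✓4∨	6✓6∨	5✓6∨	5✓5∨	7✓5∨	12✓7∨	7✓4∨	8✓5∨
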