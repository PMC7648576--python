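gene	alleles	class	function	mitotic_flag
Apc5	apc5-CA-Paps	I	Cell cycle regulation	true
Cdc27	cdc27-2	I	Cell cycle regulation	true
Cdc28	cdc28-13	I	Cell cycle regulation	true
Cdc20	cdc20-2,cdc20-3	I	Cell cycle regulation	true
Bet2	bet2-1	I	Cell transport	false
Sed5	sed5-1	I	Cell transport	false
Sft1	sft1-15	I	Cell transport	false
Abf1	abf1-102	I	Chromatin remodeling	false
Rsc8	rsc8-ts16	I	Chromatin remodeling	false
Swd2	swd2-1	I	Chromatin remodeling	false
Tel2	tel2-15	I	Chromatin remodeling	false
Ndc10	ndc10-1	I	Chromosome segregation	true
Cdc14	cdc14-8	I	Chromosome segregation	true
Cdc31	cdc31-2	I	Chromosome segregation	true
Cse4	cse4-1	I	Chromosome segregation	true
Dad2	dad2-9	I	Chromosome segregation	true
Dam1	dam1-1,dam1-19	I	Chromosome segregation	true
Duo1	duo1-2	I	Chromosome segregation	true
Eco1	eco1-1	I	Chromosome segregation	true
Esp1	esp1-1	I	Chromosome segregation	true
Ipl1	ipl1-2	I	Chromosome segregation	true
Mif2	mif2-3	I	Chromosome segregation	true
Mps1	mps1-1	I	Chromosome segregation	true
Mtw1	mtw1-ts	I	Chromosome segregation	true
Nbp1	nbp1-1	I	Chromosome segregation	false
Nnf1	nnf1-17,nnf1-48,nnf1-77	I	Chromosome segregation	true
Nsl1	nsl1-5,nsl1-6	I	Chromosome segregation	true
Nuf2	nuf2-61	I	Chromosome segregation	true
Pds1	pds1-128	I	Chromosome segregation	true
Sgt1	sgt1-3,sgt1-5	I	Chromosome segregation	false
Sli15	sli15-3	I	Chromosome segregation	false
Smc1	scm1-1	I	Chromosome segregation	true
Smc3	scm3-42	I	Chromosome segregation	true
Spc110	spc110-220	I	Chromosome segregation	true
Spc24	spc24 4-2	I	Chromosome segregation	true
Spc25	spc25-1	I	Chromosome segregation	true
Spc29	spc29-20	I	Chromosome segregation	false
Spc34	spc34 41-1	I	Chromosome segregation	true
Stu1	stu1-12,stu1-5,stu1-6,stu1-7	I	Chromosome segregation	true
Stu2	stu2-11,stu2-13	I	Chromosome segregation	true
Dbf4	dbf4-2,dbf4-3,dbf4-ts	I	Chromosome segregation	true
Smt3	smt3-42	I	Chromosome segregation	true
Cdc6	cdc6-1	I	DNA replication	true
Cdc7	cdc7-4	I	DNA replication	true
Cdc21	cdc21-ts	I	DNA replication	false
Psf1	psf1-1	I	DNA replication	false
Kre5	kre5-ts2	I	Metabolism	false
Krr1	krr1-18	I	Nucleolar and ribosome	false
Nog2	nog2-1	I	Nucleolar and ribosome	false
Nop2	nop2-5,nop2-9	I	Nucleolar and ribosome	false
Nop7	nop7-1	I	Nucleolar and ribosome	false
Rrp5	rrp5-delta6	I	Nucleolar and ribosome	false
Arp3	arp3-G302Y	I	Polarity	false
Cdc24	cdc24-5	I	Polarity	true
Cdc43	cdc43-2	I	Polarity	false
Exo70	exo70-20/37	I	Polarity	false
Pan1	pan1-4	I	Polarity	true
Sec23	sec23-1	I	Polarity	false
Cdc34	cdc34-1	I	Protein degradation	true
Met30	met30-6	I	Protein degradation	false
Pre2	pre2-75	I	Protein degradation	false
Rpt6	rpt6-20	I	Protein degradation	false
Gpi13	gpi13-5	I	Protein modification	false
Sec53	sec53-6	I	Protein modification	false
Cdc39	cdc39-1	I	Transcription and RNA	false
Hts1	hst1-1	I	Transcription and RNA	false
Prp19	prp19-1	I	Transcription and RNA	false
Prp2	prp2-1	I	Transcription and RNA	false
Rse1	rse1-1	I	Transcription and RNA	false
Slu7	slu7-ts2	I	Transcription and RNA	false
Ssl2	ssl2-ts	I	Transcription and RNA	false
Ssu72	ssu72-2	I	Transcription and RNA	false
Yhc1	ych1-1	I	Transcription and RNA	false
Pob3	pob3-7,pob3-L78R	II	Chromatin remodeling	false
Spt16	spt16-1	II	Chromatin remodeling	false
Crm1	crm1-1	III	Nuclear transport	false
Rna1	rna1-1	III	Nuclear transport	false
Srm1	srm1-ts	III	Nuclear transport	false
Yrb1	yrb1-51	III	Nuclear transport	false
Hym1	hym1-15	III	Polarity	false
Mob2	mob2-14,mob2-19,mob2-22,mob2-28,mob2-36,mob2-38	III	Polarity	false
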