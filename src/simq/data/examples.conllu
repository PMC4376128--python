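# qid = fig2
1	could	_	MD	_	_	3	aux	_	_
2	chronic_arthritis	_	NN	_	_	3	nsubj	_	_
3	cause	_	VB	_	_	0	root	_	_
4	constant_pain	_	NN	_	_	3	dobj	_	_
5	below	_	IN	_	_	7	case	_	_
6	the	_	DT	_	_	7	det	_	_
7	left_knee	_	NN	_	_	4	nmod	_	_

# qid = hbp-1
1	could	_	MD	_	_	4	aux	_	_
2	my	_	PRP$	_	_	3	nmod:poss	_	_
3	blurred_eyes	_	NN	_	_	4	nsubj:pass	_	_
4	caused	_	VBN	_	_	0	root	_	_
5	by	_	IN	_	_	6	case	_	_
6	hypertension	_	NN	_	_	4	obl	_	_

# qid = hbp-2
1	hbp	_	NN	_	_	2	nsubj	_	_
2	lead	_	VB	_	_	0	root	_	_
3	to	_	IN	_	_	4	case	_	_
4	blurry_vision	_	NN	_	_	2	obl	_	_

# qid = folic
1	could	_	MD	_	_	3	aux	_	_
2	folic_acid	_	NN	_	_	3	nsubj	_	_
3	cause	_	VB	_	_	0	root	_	_
4	a	_	DT	_	_	5	det	_	_
5	bitter_taste	_	NN	_	_	3	dobj	_	_
6	and	_	CC	_	_	7	cc	_	_
7	body_odor	_	NN	_	_	5	conj	_	_
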