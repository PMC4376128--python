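# Bundled fixture lexicon covering the package's worked examples.
# CUIs in the C9xxxxxx range are synthetic placeholders for terms whose
# published identifiers are not enumerated anywhere we reproduce.
term	cui	semantic_type
folic acid	C0016410	Pharmacologic Substance
cause	C0678227	Functional Concept
lead	C0678227	Functional Concept
bitter taste	C0235290	Sign and Symptom
body odor	C0085595	Finding
blurred vision	C0344232	Sign or Symptom
blurred eyes	C0344232	Sign or Symptom
blurry vision	C0344232	Sign or Symptom
hypertension	C0020538	Disease or Syndrome
hypertensive disease	C0020538	Disease or Syndrome
hbp	C0020538	Disease or Syndrome
lose weight	C0043096	Finding
gain weight	C0043094	Finding
breast lump	C0424849	Finding
swelling	C0038999	Finding
breast cancer	C0006142	Neoplastic Process
tumor	C0027651	Neoplastic Process
chronic arthritis	C9000001	Disease or Syndrome
constant pain	C9000002	Finding
below	C9000003	Spatial Concept
left knee	C9000004	Body Location or Region
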