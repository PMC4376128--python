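# token -> normal form; overrides the suffix rules
# -e stem verbs (dropping "ed"/"es" outright would lose the final e)
caused	cause
causes	cause
used	use
uses	use
increased	increase
increases	increase
decreased	decrease
decreases	decrease
# non-plural words ending in s
arthritis	arthritis
diabetes	diabetes
herpes	herpes
measles	measles
mumps	mumps
rabies	rabies
scabies	scabies
species	species
pancreas	pancreas
virus	virus
lens	lens
gas	gas
news	news
is	is
his	his
this	this
thus	thus
was	was
has	has
does	do
yes	yes
plus	plus
always	always
perhaps	perhaps
# irregular plurals
feet	foot
teeth	tooth
children	child
women	woman
men	man
people	person
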