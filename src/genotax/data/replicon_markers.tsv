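# Controlled vocabulary of replicon-classification marker genes.
# category: chromosome = core housekeeping genes / rRNA operon components;
#           plasmid    = conjugation and type IV secretion system genes.
gene	category
dnaa	chromosome
gyra	chromosome
gyrb	chromosome
rpob	chromosome
reca	chromosome
rrs_16s	chromosome
rrl_23s	chromosome
para	chromosome
parb	chromosome
virb2	plasmid
virb4	plasmid
virb9	plasmid
virb11	plasmid
vird4	plasmid
trag	plasmid
tral	plasmid
trba	plasmid
repa	plasmid
repb	plasmid
repc	plasmid
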