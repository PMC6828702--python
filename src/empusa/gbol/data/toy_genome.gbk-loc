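# Toy annotation: one feature per line, <feature-id>	<key>	<GenBank location>
gene1	gene	100..200
gene2	gene	complement(300..400)
gene3	gene	join(500..550,600..650)
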