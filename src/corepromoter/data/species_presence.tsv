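species	en	drm	Sema5c	Ppa	Cad74A	noc	opa
Drosophila melanogaster	+	+	+	+	+	+	+
Drosophila simulans	+	+	+	-	+	+	+
Drosophila sechellia	+	+	+	+	+	+	+
Drosophila yakuba	+	+	+	+	+	+	+
Drosophila erecta	+	+	+	+	+	+	+
Drosophila biarmipes	+	+	+	-	+	+	+
Drosophila suzukii	+	+	+	+	-	+	-
Drosophila ananassae	+	+	+	+	+	-	+
Drosophila bipectinata	+	+	+	+	-	+	-
Drosophila eugracilis	+	+	+	+	+	+	+
Drosophila elegans	+	+	+	+	+	+	+
Drosophila kikkawai	+	+	+	-	+	+	+
Drosophila takahashii	+	+	+	-	+	+	+
Drosophila rhopaloa	+	+	+	+	+	+	+
Drosophila ficusphila	+	+	+	-	+	+	+
Drosophila pseudoobscura	+	+	-	-	+	+	+
Drosophila persimilis	+	+	-	-	+	+	+
Drosophila miranda	+	+	-	+	+	+	+
Drosophila willistoni	+	-	+	-	-	+	+
Drosophila virilis	+	+	+	-	+	+	+
Drosophila mojavensis	+	-	-	-	+	+	+
Drosophila albomicans	-	-	-	-	+	+	+
Drosophila grimshawi	+	+	-	-	+	-	-
Musca domestica	+	+	-	+	-	+	-
Anopheles gambiae	-	-	-	-	-	-	-
Apis mellifera	-	-	-	-	-	-	-
Tribolium castaneum	-	-	-	-	-	-	-
Aedes aegypti	-	-	+	-	-	-	-
Aedes albopictus	-	-	-	-	-	-	+
Anoplophora glabripennis	-	+	-	-	-	-	-
Bactrocera dorsalis	-	-	-	+	+	-	+
Bactrocera latifrons	+	-	-	+	-	+	-
Bactrocera oleae	-	-	-	+	+	-	-
Ceratitis capitata	-	-	-	-	+	+	+
Dendroctonus ponderosae	-	+	-	-	-	-	-
Lucilia cuprina	-	-	+	+	-	-	+
Plutella xylostella	-	+	-	-	-	-	-
Rhagoletis zephyria	-	+	-	-	+	+	-
Stomoxys calcitrans	+	-	-	-	-	+	-
Zeugodacus cucurbitae	-	-	-	-	+	+	-
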