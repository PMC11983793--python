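# name	smiles	class
gallic acid	OC(=O)c1cc(O)c(O)c(O)c1	phenolic_acid
quercetin	O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O	flavonoid
ferulic acid	COc1cc(/C=C/C(=O)O)ccc1O	hydroxycinnamic_acid_derivative
catechol	Oc1ccccc1O	hydroxybenzene
resveratrol	Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	stilbene
umbelliferone	O=C1C=Cc2ccc(O)cc2O1	coumarin
coumestrol	O=C1Oc2cc(O)ccc2C2=C1c1ccc(O)cc1O2	coumestan
secoisolariciresinol	COc1cc(CC(CO)C(CO)Cc2ccc(O)c(OC)c2)ccc1O	lignan
juglone	O=C1C=CC(=O)c2c(O)cccc21	naphthoquinone
curcumin	COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O	curcuminoid
butein	O=C(c1ccc(O)cc1O)/C=C/c1ccc(O)c(O)c1	chalcone
mandelic acid	OC(C(=O)O)c1ccccc1	other
p-coumaric acid	OC(=O)/C=C/c1ccc(O)cc1	hydroxycinnamic_acid_derivative
catechin	OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1	flavonoid
caffeic acid	OC(=O)/C=C/c1ccc(O)c(O)c1	hydroxycinnamic_acid_derivative
thymol	Cc1ccc(C(C)C)c(O)c1	hydroxybenzene
salicylic acid	OC(=O)c1ccccc1O	phenolic_acid
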