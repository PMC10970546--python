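name	formula	compound_class	superclass
Lactacystin	C15H24N2O7S	Carboxylic acids and derivatives	Organic acids and derivatives
Taurine	C2H7NO3S	Organic sulfonic acids and derivatives	Organic acids and derivatives
Styrene oxide	C8H8O	Benzene and substituted derivatives	Benzenoids
Tyramine	C8H11NO	Benzene and substituted derivatives	Benzenoids
Setanaxib	C21H19ClN4O2	Pyridines and derivatives	Organoheterocyclic compounds
Norsalsolinol	C9H11NO2	Tetrahydroisoquinolines	Organoheterocyclic compounds
Ganoderic acid V	C32H48O6	Prenol lipids	Lipids and lipid-like molecules
Ganglioside GM1 (d18:0/16:0)	C72H130N2O31	Sphingolipids	Lipids and lipid-like molecules
gamma-Glutamylcysteine	C8H14N2O5S	Carboxylic acids and derivatives	Organic acids and derivatives
Tyrosyl-Serine	C12H16N2O5	Carboxylic acids and derivatives	Organic acids and derivatives
Acetyl citrate	C8H10O8	Carboxylic acids and derivatives	Organic acids and derivatives
Ginsenoside Rh1	C36H62O9	Prenol lipids	Lipids and lipid-like molecules
Theasapogenol A	C30H50O6	Prenol lipids	Lipids and lipid-like molecules
Phosphatidic acid	C37H71O8P	Glycerophospholipids	Lipids and lipid-like molecules
Ursodeoxycholic acid	C24H40O4	Steroids and steroid derivatives	Lipids and lipid-like molecules
Polyporusterone F	C28H46O5	Steroids and steroid derivatives	Lipids and lipid-like molecules
Brassinolides	C27H46O6	Steroids and steroid derivatives	Lipids and lipid-like molecules
10-Hydroperoxy-H4-neuroprostane	C22H32O6	Fatty acyls	Lipids and lipid-like molecules
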