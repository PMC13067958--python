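bacteriocin_name	subclass
Nisin A	I
Nisin F	I
Lacticin 3147 A1	I
Lacticin 3147 A2	I
Mutacin II	I
Pediocin	IIa
Sakacin P	IIa
Sakacin G	IIa
Sakacin Q	IIa
Curvacin A	IIa
Plantaricin 423	IIa
Pentocin	IIa
Enterocin NKR-5-3A	IIa
Plantaricin E	IIb
Plantaricin F	IIb
Plantaricin J	IIb
Plantaricin K	IIb
Plantaricin NC8 α	IIb
Plantaricin NC8 β	IIb
Plantaricin S α	IIb
Plantaricin S β	IIb
Enterocin X α	IIb
Enterocin X β	IIb
Lactacin F lafA	IIb
Brochocin C	IIb
MR10B	IIb
Acidocin LF221B	IIb
Salivaricin P	IIb
Salivaricin B	IIb
Acidocin B	IIc
Gassericin A	IIc
Plantaricin A	IId
Lacticin Z	IId
Closticin 574	IId
Bovicin 255	IId
Acidocin LF221A	IIb
Enterolysin A	III
Helveticin J	III
Zoocin A	III
Carnocin CP52	other
LSEI 2386	other
LS2 bacteriocin	other
Putative bacteriocin	other
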