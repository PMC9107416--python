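# 13-region brainstem catalog. The spinal trigeminal nucleus (sTN) and
# nucleus tractus solitarius (NTS) spheres (radius 3 mm) follow published
# MNI coordinates. The remaining nuclei are normally taken from the AAL
# (red nucleus, substantia nigra) and Harvard AAN (dorsal raphe, locus
# coeruleus, periaqueductal grey, parabrachial complex, ventral tegmental
# area) atlases, which cannot be redistributed; the rows below are
# SYNTHETIC sphere stand-ins at approximate nucleus locations. Supply the
# real atlases as label volumes for exact masks.
name	kind	x	y	z	radius_mm	label_id
sTN_L	sphere	-2	-44	-62	3
sTN_R	sphere	2	-44	-62	3
NTS_L	sphere	-8	-38	-42	3
NTS_R	sphere	8	-38	-42	3
RN_L	sphere	-5	-24	-8	3
RN_R	sphere	5	-24	-8	3
SN_L	sphere	-10	-18	-12	3
SN_R	sphere	10	-18	-12	3
DR	sphere	0	-30	-22	3
LC	sphere	0	-37	-25	3
PAG	sphere	0	-29	-12	3
PBA	sphere	0	-34	-26	3
VTA	sphere	0	-16	-12	3
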