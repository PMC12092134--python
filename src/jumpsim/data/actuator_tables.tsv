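# Reference actuator architecture tables for the human and guineafowl
# planar biped models (single limb).  fl_mm: fibre length from the
# range-of-motion method.  m1/m2/m3: PCSA in mm^2 under the measured,
# schematic-partitioning and regression-predicted reconstructions.
# actions: joint:role pairs separated by ';' (role extensor|flexor;
# plantarflexion counts as extension).  region: proximal|distal limb.
taxon	actuator	region	fl_mm	m1	m2	m3	actions
human	hip ext	proximal	172.295	5534.583	8125.023	6195.388	hip:extensor
human	hip ext knee flx	proximal	123.632	6444.721	14425.111	3052.271	hip:extensor;knee:flexor
human	hip flx	proximal	45.389	33435.136	16607.251	19982.571	hip:flexor
human	hip flx knee ext	proximal	138.213	1913.731	13183.589	880.254	hip:flexor;knee:extensor
human	knee ext	proximal	129.079	13922.225	8276.688	15344.503	knee:extensor
human	knee flx	proximal	108.875	1454.071	3522.453	1022.853	knee:flexor
human	knee flx ankle ext	distal	59.142	7891.753	20811.168	19720.55	knee:flexor;ankle:extensor
human	ankle ext	distal	50.426	16678.017	16803.977	35014.739	ankle:extensor
human	ankle flx	distal	28.742	6597.919	31747.279	38448.22	ankle:flexor
guineafowl	hip ext	proximal	20.854	566.144	930.188	282.115	hip:extensor
guineafowl	hip ext knee ext	proximal	33.814	594.958	1003.959	116.584	hip:extensor;knee:extensor
guineafowl	hip ext knee flx	proximal	29.682	1457.053	1049.824	289.241	hip:extensor;knee:flexor
guineafowl	hip flx	proximal	8.426	1625.218	1861.331	559.835	hip:flexor
guineafowl	hip flx knee ext	proximal	42.968	343.063	703.599	109.607	hip:flexor;knee:extensor
guineafowl	knee ext	proximal	15.383	1326.183	945.784	272.122	knee:extensor
guineafowl	knee flx ankle ext	distal	18.790	948.424	1401.101	362.748	knee:flexor;ankle:extensor
guineafowl	ankle ext	distal	17.639	992.099	825.64	635.110	ankle:extensor
guineafowl	ankle flx	distal	18.304	280.401	856.851	215.809	ankle:flexor
guineafowl	pes dfx	distal	18.263	18.289	429.374	156.694	tmtp:flexor
guineafowl	pes pfx	distal	24.436	186.948	595.992	522.668	tmtp:extensor
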