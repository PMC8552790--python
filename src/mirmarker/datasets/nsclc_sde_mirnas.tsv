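mirna	pvalue	log2fc	snr	status
hsa-miR-21-5p	3.62E-87	1.019878	1.991775	Up
hsa-miR-30a-5p	2.91E-202	-2.95875	1.503804	Down
hsa-miR-96-5p	1.13E-152	2.589762	1.151469	Up
hsa-miR-30d-5p	2.28E-174	-1.8064	2.275344	Down
hsa-miR-183-5p	1.42E-144	2.43937	1.126407	Up
hsa-miR-210-3p	4.49E-175	4.419388	1.188131	Up
hsa-miR-218-5p	5.53E-217	-2.25307	1.9371	Down
hsa-miR-1-3p	1.94E-254	-2.53346	3.092538	Down
hsa-miR-30b-5p	6.69E-103	-1.35847	1.673761	Down
hsa-miR-141-3p	5.45E-125	1.475862	1.273509	Up
hsa-miR-144-3p	3.63E-161	-3.18641	1.282499	Down
hsa-miR-145-5p	2.16E-111	-1.34576	1.850366	Down
hsa-miR-126-3p	9.74E-87	-1.43099	1.124842	Down
hsa-miR-451a	4.11E-149	-3.34021	1.172588	Down
hsa-miR-708-5p	2.22E-141	3.087151	1.051665	Up
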