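# Physiology of six recombinant S. cerevisiae strains: two hosts (CTY, INVSc1)
# each carrying the wild-type (WT) or a promoter-optimized (CTYp, INVp) fungal
# xylose pathway.  mu: specific growth rate (1/h); q_xylose: specific xylose
# uptake rate (mmol/gDCW/h); y_*: product yields (g/g).  *_sd columns are the
# stated +/- uncertainties.
strain	mu	mu_sd	q_xylose	q_xylose_sd	y_xylitol	y_xylitol_sd	y_glycerol	y_glycerol_sd	y_acetate	y_acetate_sd	y_etoh	y_etoh_sd
CTY-WT	0.007	0.005	0.16	0.02	0.04	0.00	0.00	0.00	0.00	0.00	0.00	0.00
CTY-CTYp	0.024	0.002	0.60	0.02	0.12	0.01	0.00	0.00	0.00	0.00	0.25	0.01
CTY-INVp	0.016	0.006	0.44	0.00	0.00	0.00	0.05	0.04	0.00	0.00	0.00	0.00
INV-WT	0.015	0.003	0.28	0.01	0.05	0.00	0.06	0.00	0.00	0.00	0.15	0.06
INV-CTYp	0.028	0.002	0.43	0.05	0.07	0.00	0.06	0.00	0.00	0.00	0.21	0.01
INV-INVp	0.031	0.006	0.55	0.04	0.02	0.01	0.05	0.00	0.02	0.00	0.29	0.04
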