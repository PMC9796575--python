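# Layered interstitial-space measurements, Chaohu Lake sediment cores.
# Values are means of five replicates per site x 5-cm layer; NA marks layers
# that could not be measured (disturbed core sections or gas below detection).
# water_depth_cm: site2=225 site3=255 site4=130 site5=300
# temperature_c: site2=24.6-25.2 site3=24.7-25.2 site4=27.1-28.0 site5=24.1-24.4
site_id	depth_cm	variable	value	replicate
site2	2.5	tis	72.4
site2	2.5	vwc	65.7
site2	2.5	gas_space	6.67
site2	2.5	p_size	43.99
site2	2.5	p_evenness	1.00
site2	7.5	tis	75.5
site2	7.5	vwc	59.5
site2	7.5	gas_space	16.03
site2	7.5	p_size	28.87
site2	7.5	p_evenness	0.87
site2	12.5	tis	72.0
site2	12.5	vwc	60.9
site2	12.5	gas_space	11.09
site2	12.5	p_size	23.99
site2	12.5	p_evenness	0.92
site2	17.5	tis	62.1
site2	17.5	vwc	55.3
site2	17.5	gas_space	6.81
site2	17.5	p_size	71.58
site2	17.5	p_evenness	0.94
site2	22.5	tis	66.5
site2	22.5	vwc	53.3
site2	22.5	gas_space	13.19
site2	22.5	p_size	42.40
site2	22.5	p_evenness	1.16
site2	27.5	tis	NA
site2	27.5	vwc	NA
site2	27.5	gas_space	NA
site2	27.5	p_size	338.60
site2	27.5	p_evenness	0.76
site2	32.5	tis	NA
site2	32.5	vwc	NA
site2	32.5	gas_space	NA
site2	32.5	p_size	162.48
site2	32.5	p_evenness	1.02
site2	37.5	tis	60.6
site2	37.5	vwc	51.8
site2	37.5	gas_space	8.82
site2	37.5	p_size	62.13
site2	37.5	p_evenness	1.37
site2	42.5	tis	57.6
site2	42.5	vwc	49.3
site2	42.5	gas_space	8.28
site2	42.5	p_size	66.55
site2	42.5	p_evenness	1.30
site3	2.5	tis	67.9
site3	2.5	vwc	67.9
site3	2.5	gas_space	0
site3	2.5	p_size	37.68
site3	2.5	p_evenness	1.12
site3	7.5	tis	76.8
site3	7.5	vwc	58.9
site3	7.5	gas_space	17.93
site3	7.5	p_size	67.90
site3	7.5	p_evenness	1.38
site3	12.5	tis	63.6
site3	12.5	vwc	58.1
site3	12.5	gas_space	5.52
site3	12.5	p_size	69.29
site3	12.5	p_evenness	1.00
site3	17.5	tis	61.8
site3	17.5	vwc	55.3
site3	17.5	gas_space	6.53
site3	17.5	p_size	64.32
site3	17.5	p_evenness	1.20
site3	22.5	tis	65.6
site3	22.5	vwc	61.6
site3	22.5	gas_space	4.01
site3	22.5	p_size	39.58
site3	22.5	p_evenness	1.14
site3	27.5	tis	70.7
site3	27.5	vwc	62.9
site3	27.5	gas_space	7.79
site3	27.5	p_size	40.27
site3	27.5	p_evenness	1.11
site3	32.5	tis	67.6
site3	32.5	vwc	60.2
site3	32.5	gas_space	7.43
site3	32.5	p_size	34.98
site3	32.5	p_evenness	1.06
site3	37.5	tis	70.5
site3	37.5	vwc	61.4
site3	37.5	gas_space	9.07
site3	37.5	p_size	32.50
site3	37.5	p_evenness	1.18
site3	42.5	tis	65.2
site3	42.5	vwc	62.6
site3	42.5	gas_space	2.57
site3	42.5	p_size	30.82
site3	42.5	p_evenness	1.10
site4	2.5	tis	67.4
site4	2.5	vwc	67.4
site4	2.5	gas_space	0
site4	2.5	p_size	30.77
site4	2.5	p_evenness	1.10
site4	7.5	tis	69.2
site4	7.5	vwc	64.5
site4	7.5	gas_space	4.73
site4	7.5	p_size	23.95
site4	7.5	p_evenness	1.09
site4	12.5	tis	69.9
site4	12.5	vwc	63.3
site4	12.5	gas_space	6.62
site4	12.5	p_size	27.60
site4	12.5	p_evenness	1.22
site4	17.5	tis	69.6
site4	17.5	vwc	59.5
site4	17.5	gas_space	10.05
site4	17.5	p_size	29.31
site4	17.5	p_evenness	1.11
site4	22.5	tis	61.3
site4	22.5	vwc	54.4
site4	22.5	gas_space	6.92
site4	22.5	p_size	25.25
site4	22.5	p_evenness	0.95
site4	27.5	tis	62.4
site4	27.5	vwc	55.3
site4	27.5	gas_space	7.09
site4	27.5	p_size	21.30
site4	27.5	p_evenness	0.99
site4	32.5	tis	59.3
site4	32.5	vwc	54.2
site4	32.5	gas_space	5.10
site4	32.5	p_size	21.58
site4	32.5	p_evenness	1.00
site4	37.5	tis	59.0
site4	37.5	vwc	56.1
site4	37.5	gas_space	2.91
site4	37.5	p_size	16.62
site4	37.5	p_evenness	0.97
site4	42.5	tis	56.1
site4	42.5	vwc	53.6
site4	42.5	gas_space	2.49
site4	42.5	p_size	15.13
site4	42.5	p_evenness	0.94
site5	2.5	tis	88.2
site5	2.5	vwc	88.2
site5	2.5	gas_space	NA
site5	2.5	p_size	9.52
site5	2.5	p_evenness	1.39
site5	7.5	tis	88.2
site5	7.5	vwc	88.2
site5	7.5	gas_space	NA
site5	7.5	p_size	8.56
site5	7.5	p_evenness	1.47
site5	12.5	tis	84.9
site5	12.5	vwc	84.9
site5	12.5	gas_space	NA
site5	12.5	p_size	11.13
site5	12.5	p_evenness	1.64
site5	17.5	tis	73.3
site5	17.5	vwc	73.3
site5	17.5	gas_space	NA
site5	17.5	p_size	13.92
site5	17.5	p_evenness	1.55
site5	22.5	tis	64.4
site5	22.5	vwc	62.0
site5	22.5	gas_space	2.4
site5	22.5	p_size	14.32
site5	22.5	p_evenness	1.61
site5	27.5	tis	61.2
site5	27.5	vwc	61.2
site5	27.5	gas_space	NA
site5	27.5	p_size	14.76
site5	27.5	p_evenness	1.61
site5	32.5	tis	64.4
site5	32.5	vwc	60.0
site5	32.5	gas_space	4.4
site5	32.5	p_size	13.31
site5	32.5	p_evenness	1.57
site5	37.5	tis	65.7
site5	37.5	vwc	60.7
site5	37.5	gas_space	5.0
site5	37.5	p_size	7.32
site5	37.5	p_evenness	0.91
site5	42.5	tis	61.8
site5	42.5	vwc	61.8
site5	42.5	gas_space	NA
site5	42.5	p_size	10.23
site5	42.5	p_evenness	1.30
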