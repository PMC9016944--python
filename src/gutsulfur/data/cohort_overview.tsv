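# Published per-study cohort overview: participants and MAGs per study and
# disease state across the five public CRC metagenome cohorts.
study	country	disease_state	n_participants	n_mags
Feng	Austria	healthy	61	1690
Feng	Austria	adenoma	47	1421
Feng	Austria	carcinoma	46	1418
Hannigan	USA/Canada	healthy	26	101
Hannigan	USA/Canada	adenoma	23	57
Hannigan	USA/Canada	carcinoma	26	78
Vogtmann	USA	healthy	58	1863
Vogtmann	USA	adenoma	0	0
Vogtmann	USA	carcinoma	52	1622
Yu	China	healthy	54	1397
Yu	China	adenoma	0	0
Yu	China	carcinoma	75	1910
Zeller	France	healthy	66	1839
Zeller	France	adenoma	42	956
Zeller	France	carcinoma	91	2584
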