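reference_strain	I-1	I-2	I-4	I-5	II-2	III-1	III-2
B. barranii ssp. barranii 144S4	96.31	96.38	96.32	96.31	96.30	96.36	96.31
B. barranii ssp. apii 38S5	95.49	95.54	95.53	95.51	95.46	95.54	95.48
B. japonicum USDA 6	95.42	95.40	95.36	95.45	95.41	95.43	95.40
B. diazoefficiens USDA 110	89.58	89.51	89.49	89.56	89.64	89.47	89.46
B. ottawaense OO99	89.02	89.02	89.04	89.08	89.15	89.04	89.08
B. xenonodulans 14AB	89.15	89.08	89.04	89.14	89.03	89.05	89.08
B. niftali CNPSo 3448	88.74	88.79	88.76	88.77	88.77	88.75	88.78
B. betae PL7HG1	88.74	88.76	88.78	88.79	88.76	88.80	88.66
B. liaoningense NBRC 100396	88.40	88.42	88.49	88.38	88.58	88.41	88.46
B. elkanii USDA 76	80.71	81.16	80.78	80.86	81.33	80.79	81.09
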