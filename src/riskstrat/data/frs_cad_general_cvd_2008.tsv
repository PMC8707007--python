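# Sex-specific Framingham general cardiovascular disease risk function
# (continuous Cox form, 10-year horizon; D'Agostino et al., Circulation 2008).
# Lipids enter as ln(mg/dL); SBP as ln(mmHg); age as ln(years).
# risk = 1 - baseline_survival ^ exp(lp - mean_lp)
sex	term	value
female	ln_age	2.32888
female	ln_total_chol	1.20904
female	ln_hdl	-0.70833
female	ln_sbp_untreated	2.76157
female	ln_sbp_treated	2.82263
female	smoker	0.52873
female	diabetes	0.69154
female	baseline_survival	0.95012
female	mean_lp	26.1931
male	ln_age	3.06117
male	ln_total_chol	1.12370
male	ln_hdl	-0.93263
male	ln_sbp_untreated	1.93303
male	ln_sbp_treated	1.99881
male	smoker	0.65451
male	diabetes	0.57367
male	baseline_survival	0.88936
male	mean_lp	23.9802
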