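# SYNTHETIC stand-in coefficient file for a near-term incident-hypertension
# logistic risk equation.  Same predictors as the Framingham hypertension
# risk score (Parikh et al., Ann Intern Med 2008), but the coefficients
# here were calibrated once to a prehypertensive middle-aged cohort (most
# of such a cohort lands above the 10% cutpoint, as reported for the
# published score); they are NOT the published values.  Replace this file
# with transcribed published coefficients for real use.
# risk = expit(sum coef * (x - center)).
term	coefficient	center
intercept	-1.4	0
age	0.06	56.3
male	0.2	0
parental_history	0.5	0
bmi	0.05	26.8
sbp	0.08	130
dbp	0.06	80
smoker	0.3	0
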