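# SYNTHETIC stand-in coefficient file for an 8-year incident-diabetes
# logistic risk equation.  Same predictors and functional form as the
# Framingham Offspring "simple clinical model" (Wilson et al., Arch Intern
# Med 2007), but the coefficients here were chosen to give a plausible
# absolute-risk distribution in a middle-aged population cohort; they are
# NOT the published values.  Replace this file with transcribed published
# coefficients for real use.  risk = expit(sum coef * (x - center)).
term	coefficient	center
intercept	-3.66	0
age	0.04	56.3
male	0.2	0
parental_history	0.55	0
bmi	0.09	26.8
hdl	-0.9	1.47
triglycerides	0.25	1.68
fasting_glucose	0.9	5.0
elevated_bp	0.3	0
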