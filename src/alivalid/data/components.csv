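name,system,threshold,direction,threshold_male,threshold_female,anchors
systolic_bp,cardiovascular,140,greater,,,Hypertension
diastolic_bp,cardiovascular,90,greater,,,Hypertension
bmi,metabolic,30,greater,,,"Obesity|Morbid obesity|Grade I, II or III obesity"
triglycerides,metabolic,150,greater_equal,,,Hypertriglyceridemia
total_cholesterol,metabolic,200,greater_equal,,,Hypercholesterolemia
crp,inflammation,10,greater_equal,,,Sepsis|Infection|Auto-immune inflammatory syndrome
hba1c,inflammation,6.5,greater_equal,,,Diabetes|Impaired glycemic control
serum_albumin,inflammation,3.5,greater_equal,,,
creatinine_clearance,inflammation,,less,110,100,Renal failure|Insufficiency|Acute kidney injury|Chronic renal failure
homocysteine,inflammation,50,greater,,,Hyperhomocysteinemia|Vitamin deficiency
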