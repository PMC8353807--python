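drug_name,category
gentamicin,high_nephrotoxic
tobramycin,high_nephrotoxic
amikacin,high_nephrotoxic
vancomycin,high_nephrotoxic
amphotericin_b,high_nephrotoxic
cisplatin,high_nephrotoxic
ifosfamide,high_nephrotoxic
acyclovir,high_nephrotoxic
tacrolimus,high_nephrotoxic
cyclosporine,high_nephrotoxic
ketorolac,high_nephrotoxic
ibuprofen,low_nephrotoxic
furosemide,low_nephrotoxic
captopril,low_nephrotoxic
enalapril,low_nephrotoxic
lisinopril,low_nephrotoxic
piperacillin_tazobactam,low_nephrotoxic
trimethoprim_sulfamethoxazole,low_nephrotoxic
ceftriaxone,low_nephrotoxic
cefotaxime,low_nephrotoxic
omeprazole,low_nephrotoxic
ranitidine,low_nephrotoxic
epinephrine,vasoactive
norepinephrine,vasoactive
dopamine,vasoactive
dobutamine,vasoactive
vasopressin,vasoactive
milrinone,vasoactive
phenylephrine,vasoactive
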