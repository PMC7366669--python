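case_id,fixation,hemisphere,age_years,sex,pmd_hours
H169,formalin-fixed frozen,Right,81,Male,24
H187,formalin-fixed frozen,Left,98,Female,15
H196,formalin-fixed frozen,Left,85,Male,15
H241,formalin-fixed frozen,Right,76,Female,12
H243,formalin-fixed frozen,Right,77,Female,13
H229,paraffin-embedded,Right,88,Female,17
H230,paraffin-embedded,Right,57,Female,32
H240,paraffin-embedded,Right,73,Male,27
H242,paraffin-embedded,Right,61,Male,20
H244,paraffin-embedded,Right,76,Male,16
H246,paraffin-embedded,Right,89,Male,17
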