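# Bundled numeric diagnosis rules with confidence (pr, percent) and support (pa, participants).
if distance_traveled_from_home > 4.5 then more likely healthy  # pr=100.00 pa=6
if distance_traveled_variance > 8.0 and physical_activity_level <= 5.5 then more likely healthy  # pr=91.67 pa=12
if physical_activity_level <= 1.5 and EMA_compliance <= 9.5 then more likely mild cognitive impairment  # pr=85.71 pa=7
if mental_sharpness_variance > 2.5 and mental_sharpness_mean > 4.5 then more likely mild cognitive impairment  # pr=83.33 pa=6
if shape_score_sd <= 2.5 and mental_sharpness_variance <= 2.5 then more likely healthy  # pr=81.82 pa=22
if distance_traveled_variance > 8.0 then more likely healthy  # pr=80.00 pa=15
if mental_sharpness_variance <= 2.5 and mental_sharpness_mean <= 4.5 then more likely mild cognitive impairment  # pr=80.00 pa=5
if mental_sharpness_mean > 5.5 and physical_activity_variance <= 8.0 then more likely healthy  # pr=79.17 pa=24
if sex = male and age <= 79.5 then more likely mild cognitive impairment  # pr=77.78 pa=9
if mental_sharpness_variance > 2.5 then more likely mild cognitive impairment  # pr=77.78 pa=9
if sex = female and shape_learning_rate <= 4.5 then more likely healthy  # pr=76.47 pa=17
if shape_score_sd > 2.5 and shape_learning_rate > 1.5 then more likely mild cognitive impairment  # pr=75.00 pa=16
if physical_activity_variance <= 0.5 then more likely mild cognitive impairment  # pr=75.00 pa=8
if mental_sharpness_mean <= 4.5 then more likely mild cognitive impairment  # pr=75.00 pa=8
if shape_score_sd > 2.5 then more likely mild cognitive impairment  # pr=70.59 pa=17
if shape_score_sd <= 2.5 then more likely healthy  # pr=60.61 pa=33
if distance_traveled_variance <= 8.0 then more likely mild cognitive impairment  # pr=60.61 pa=33
if physical_activity_variance > 0.5 then more likely healthy  # pr=57.50 pa=40
if mental_sharpness_variance <= 2.5 then more likely healthy  # pr=57.50 pa=40
if mental_sharpness_mean > 4.5 then more likely healthy  # pr=56.10 pa=41
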