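segment,sex,length_fraction,mass_fraction,com_fraction,gyration_fraction
shank,male,0.246,0.0866,0.554,0.251
thigh,male,0.245,0.2832,0.590,0.329
pelvis,male,0.094,0.1120,0.500,0.310
torso,male,0.300,0.4908,0.450,0.400
shank,female,0.242,0.0962,0.558,0.271
thigh,female,0.242,0.2956,0.595,0.369
pelvis,female,0.096,0.1240,0.500,0.330
torso,female,0.295,0.4583,0.450,0.410
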