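# SYNTHETIC standard population: a smooth stand-in age pyramid for an aging
# population, used as the default direct-standardization reference.  This is
# NOT a real census table; supply your own weights CSV for real analyses.
bin_label,weight
50~54,0.220
55~59,0.190
60~64,0.170
65~69,0.140
70~74,0.110
75~79,0.080
80~84,0.055
85~,0.035
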