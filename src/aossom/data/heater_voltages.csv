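sensor,heater_voltage_v,working_temp_c
S1,1.25,34.4
S2,1.50,36.0
S3,1.75,37.8
S4,2.00,40.4
S5,2.25,43.0
S6,2.50,48.1
S7,2.75,52.5
S8,3.00,60.0
S9,3.25,65.7
S10,3.50,74.3
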