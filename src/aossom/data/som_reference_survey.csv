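set,som_g_per_kg
training,20.51
training,27.62
training,33.50
training,20.23
training,23.11
training,24.43
training,28.71
training,26.53
training,18.88
training,26.92
training,14.97
training,20.48
training,17.69
training,13.76
training,17.38
training,19.97
training,32.13
training,29.87
training,28.85
training,39.64
training,12.37
training,17.33
training,14.22
training,22.85
training,15.49
training,22.85
training,25.27
training,22.55
training,18.13
training,20.52
training,25.20
training,23.72
training,13.44
training,16.24
training,15.67
training,41.10
training,22.31
training,20.17
training,13.29
training,19.54
training,35.55
training,36.28
training,43.85
training,19.14
training,25.42
training,19.79
training,13.79
training,15.90
training,30.71
training,19.27
training,23.16
training,30.14
training,24.76
training,23.80
training,27.95
training,20.60
training,22.88
training,24.75
training,23.46
training,18.67
training,35.38
training,16.53
training,15.32
training,16.31
training,16.74
training,17.78
training,22.89
training,14.80
training,29.65
training,38.86
training,19.750
validation,33.77
validation,12.19
validation,24.15
validation,25.11
validation,34.24
validation,21.32
validation,25.86
validation,18.94
validation,25.85
validation,25.10
validation,19.64
validation,25.94
validation,18.96
validation,17.58
validation,22.71
validation,21.50
validation,23.18
validation,38.92
validation,28.58
validation,48.79
validation,21.13
validation,28.62
validation,20.01
validation,17.78
validation,13.64
validation,21.28
validation,14.72
validation,19.37
validation,15.59
validation,15.71
validation,27.89
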