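quantity,density_multiple,Ns,value
A/rho0,1,16,0.272
A/rho0,1,40,0.129
A/rho0,1,80,0.0819
A/rho0,1,160,0.0669
A/rho0,1,333,0.0574
A/rho0,1,1000,0.0513
A/rho0,1,5000,0.0498
A/rho0,20,16,0.271
A/rho0,20,40,0.129
A/rho0,20,80,0.0817
A/rho0,20,160,0.0660
A/rho0,20,333,0.0569
A/rho0,20,1000,0.0513
A/rho0,100,16,0.270
A/rho0,100,40,0.123
A/rho0,100,80,0.0871
A/rho0,100,160,0.0727
L/rho0,1,16,1.01
L/rho0,1,40,3.30
L/rho0,1,80,7.96
L/rho0,1,160,6.62
L/rho0,1,333,5.68
L/rho0,1,1000,5.93
L/rho0,1,5000,6.08
L/rho0,20,16,1.04
L/rho0,20,40,2.64
L/rho0,20,80,6.89
L/rho0,20,160,5.84
L/rho0,20,333,5.66
L/rho0,20,1000,5.92
L/rho0,100,16,1.18
L/rho0,100,40,3.91
L/rho0,100,80,3.62
L/rho0,100,160,3.63
Gt/rho0,1,16,2.73
Gt/rho0,1,40,6.08
Gt/rho0,1,80,13.6
Gt/rho0,1,160,30.3
Gt/rho0,1,333,46.3
Gt/rho0,1,1000,64.0
Gt/rho0,1,5000,72.2
Gt/rho0,20,16,2.84
Gt/rho0,20,40,7.86
Gt/rho0,20,80,14.8
Gt/rho0,20,160,35.1
Gt/rho0,20,333,52.8
Gt/rho0,20,1000,69.6
Gt/rho0,100,16,3.11
Gt/rho0,100,40,8.62
Gt/rho0,100,80,25.9
Gt/rho0,100,160,40.5
B/rho0,1,16,0.0620
B/rho0,1,40,0.0241
B/rho0,1,80,0.0115
B/rho0,1,160,0.00499
B/rho0,1,333,0.00238
B/rho0,1,1000,0.000800
B/rho0,1,5000,0.000222
B/rho0,20,16,0.0625
B/rho0,20,40,0.0234
B/rho0,20,80,0.0114
B/rho0,20,160,0.00458
B/rho0,20,333,0.00216
B/rho0,20,1000,0.000869
B/rho0,100,16,0.0635
B/rho0,100,40,0.0249
B/rho0,100,80,0.0113
B/rho0,100,160,0.00683
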