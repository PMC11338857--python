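Name,MP,BP,WS,D,VP,MW
Thalidomide,270,509.7,0.012,1.6,1.3,258.3
Aspirin,136,140,3,1.4,0.7,180.16
Valproic Acid,120,222,1.3,0.9,0.9,144.21
Celecoxib,158,529,3.3,1.43,1.4,381.372
Leflunomide,165,289.3,21,1.392,0.6,270.207
Wortmannin,237.52,615.6,0.121,1.4,1.8,428.43
Zoledronic Acid,193,764,2,2.13,2.7,272.09
Minocycline,213,803.3,50,1.6,0.3,457.28
Metformin,223,224.1,300,1.3,1.3,129.16
Thiocolchicoside,190,929.6,10,1.2222,0.3,563.618
Noscapine,174,565.3,0.181,1.395,1.5,413.42
Nitroxoline,180,385.64,2.73,1.3907,1.0,190.16
Methotrexate,212,823,2600,1.5,0.0,454.4
Vesnarinone,238.1,678.3,0.0968,1.2,2.1,395.5
Simvastatin,135,564.9,0.0013,1.1,3.5,418.56
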