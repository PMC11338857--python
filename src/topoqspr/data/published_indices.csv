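Name,Index,Printed,Erratum,Corrected,Note
Thalidomide,ABC-R,5.9115,0,,
Thalidomide,GA,2.3429,1,20.3429,worked example computes 20.3429; leading digit dropped in print
Thalidomide,EPi1,1467,1,1.46766E45,printed without exponent; worked example gives 1.46766x10^45 (= e^104)
Thalidomide,EPi2,1430,1,1.43021E55,printed without exponent; worked example gives 1.43020x10^55 (= e^127)
Thalidomide,GAPi,570.213,0,,
Thalidomide,SDD,48.3333,0,,
Aspirin,ABC-R,3.44,0,,
Aspirin,GA,12.3833,0,,
Aspirin,EPi1,1420,1,1.14201E26,printed value inconsistent with degree spectrum (e^60)
Aspirin,EPi2,4.607,1,4.60719E28,exponent omitted in print; e^66 = 4.60718x10^28
Aspirin,GAPi,81.4590,0,,
Aspirin,SDD,32,0,,
Valproic Acid,ABC-R,1.8235,0,,
Valproic Acid,GA,5.2314,1,8.5773,inconsistent with the 10-atom skeleton and with the row's EPi2 = e^39
Valproic Acid,EPi1,3.1856,1,3.18559E16,exponent omitted in print; e^38 = 3.18559x10^16
Valproic Acid,EPi2,8.659e16,0,,
Valproic Acid,GAPi,0.8000,1,12.8003,inconsistent with the skeleton's partition (class-wise product 12.7991)
Valproic Acid,SDD,22,0,,
Celecoxib,ABC-R,9.2836,1,8.5637,"row otherwise matches the standard structure (GA, SDD, EPi2=e^166) whose ABC-R is 8.5637"
Celecoxib,GA,26.4031,0,,
Celecoxib,EPi1,4.6754e64,1,4.67537E61,mantissa matches e^142 = 4.67544x10^61; printed exponent off by three
Celecoxib,EPi2,1.2384e72,0,,
Celecoxib,GAPi,1160.9528,0,,
Celecoxib,SDD,73,0,,
Leflunomide,ABC-R,5.8192,0,,
Leflunomide,GA,18.9602,0,,
Leflunomide,EPi1,2.2353e37,1,3.63797E42,printed e^86 inconsistent with the row's own EPi2 = e^112 and partition (e^98)
Leflunomide,EPi2,4.3750e48,0,,
Leflunomide,GAPi,257.9914,0,,
Leflunomide,SDD,50.8333,0,,
Wortmannin,ABC-R,10.3553,0,,
Wortmannin,GA,33.5562,0,,
Wortmannin,EPi1,8.1318e79,0,,
Wortmannin,EPi2,8.4682e102,0,,
Wortmannin,GAPi,6449.763,0,,
Wortmannin,SDD,84.3333,0,,
Zoledronic Acid,ABC-R,5.1584,0,,
Zoledronic Acid,GA,13.4822,1,14.4822,digit typo; structure gives 14.4822
Zoledronic Acid,EPi1,3.0251e36,0,,
Zoledronic Acid,EPi2,3.6379e42,0,,
Zoledronic Acid,GAPi,77.5959,1,93.1145,inconsistent with the structure's partition (class-wise product 93.1151)
Zoledronic Acid,SDD,48.75,0,,
Minocycline,ABC-R,11.6827,0,,
Minocycline,GA,35.653,0,,
Minocycline,EPi1,3.9452e88,0,,
Minocycline,EPi2,1.6575e114,0,,
Minocycline,GAPi,8774.3495,1,9030.2913,partition consistent with the rest of the row gives 9030.2597
Minocycline,SDD,99.75,0,,
Metformin,ABC-R,2.1268,0,,
Metformin,GA,7.2897,0,,
Metformin,EPi1,4.3112e15,0,,
Metformin,EPi2,4.3112e15,0,,
Metformin,GAPi,8.4853,0,,
Metformin,SDD,23,0,,
Thiocolchicoside,ABC-R,11.2285,0,,
Thiocolchicoside,GA,40.6037,0,,
Thiocolchicoside,EPi1,2.9152e89,0,,
Thiocolchicoside,EPi2,3.7465e108,0,,
Thiocolchicoside,GAPi,8294.384,0,,
Thiocolchicoside,SDD,97,0,,
Noscapine,ABC-R,9.2942,0,,
Noscapine,GA,33.1743,0,,
Noscapine,EPi1,2.7279e76,1,4.99633E74,inconsistent with that partition's degree spectrum (e^172)
Noscapine,EPi2,4.7445e94,0,,
Noscapine,GAPi,1934.7865,0,,
Noscapine,SDD,70.75,1,75.7500,digit typo 70.75 for 75.75; unique partition matching ABC-R/GA/GAPi/EPi2 has SDD 75.75
Nitroxoline,ABC-R,4.0746,0,,
Nitroxoline,GA,14.5173,0,,
Nitroxoline,EPi1,1.8587e31,0,,
Nitroxoline,EPi2,8.2230e36,0,,
Nitroxoline,GAPi,162.9196,0,,
Nitroxoline,SDD,34.6667,0,,
Methotrexate,ABC-R,9.7877,0,,
Methotrexate,GA,33.5645,0,,
Methotrexate,EPi1,9.1511e72,0,,
Methotrexate,EPi2,6.5892e83,0,,
Methotrexate,GAPi,2443.7562,0,,
Methotrexate,SDD,83.6667,0,,
Vesnarinone,ABC-R,8.5599,0,,
Vesnarinone,GA,31.254,0,,
Vesnarinone,EPi1,7.6094e66,0,,
Vesnarinone,EPi2,2.9915e79,0,,
Vesnarinone,GAPi,1440.049,0,,
Vesnarinone,SDD,70.6667,0,,
Simvastatin,ABC-R,9.6039,0,,
Simvastatin,GA,31.2514,0,,
Simvastatin,EPi1,1.2385e72,0,,
Simvastatin,EPi2,9.7793e85,0,,
Simvastatin,GAPi,1146.6172,0,,
Simvastatin,SDD,83.4167,0,,
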