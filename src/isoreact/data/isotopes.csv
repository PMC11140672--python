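element,isotope,mass,abundance
C,12C,12.0,0.9893
C,13C,13.00335484,0.0107
H,1H,1.00782503,0.999885
H,2H,2.01410178,0.000115
O,16O,15.99491462,0.99757
O,17O,16.99913176,0.00038
O,18O,17.99915961,0.00205
N,14N,14.00307401,0.99636
N,15N,15.00010890,0.00364
F,19F,18.99840322,1.0
Cl,35Cl,34.96885268,0.7576
Cl,37Cl,36.96590259,0.2424
S,32S,31.97207117,0.9499
S,33S,32.97145891,0.0075
S,34S,33.96786701,0.0425
S,36S,35.96708071,0.0001
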