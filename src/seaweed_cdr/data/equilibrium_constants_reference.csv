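# Reference values of the pinned equilibrium-constant set at S=35, T=25 degC, P=0.
# Regenerate with seaweed_cdr.carbonate.equilibrium_constants; the test suite
# checks the live code against this frozen table to 6 significant digits.
constant,value,negative_log10,description,source
k0,2.839188e-02,1.5468,CO2 solubility (mol kg-1 atm-1),Weiss (1974)
k1,1.421828e-06,5.8472,carbonic acid first dissociation; total scale,Lueker et al. (2000)
k2,1.081555e-09,8.9660,carbonic acid second dissociation; total scale,Lueker et al. (2000)
kb,2.526573e-09,8.5975,boric acid; total scale,Dickson (1990b)
kw,6.013704e-14,13.2209,water; converted SWS to total,Millero (1995)
ks,1.003021e-01,0.9987,bisulfate; free scale,Dickson (1990a)
kf,2.261098e-03,2.6457,hydrogen fluoride; free scale,Perez & Fraga (1987)
kp1,2.387962e-02,1.6220,phosphoric acid first; SWS to total,Millero (1995)
kp2,1.066878e-06,5.9719,phosphoric acid second; SWS to total,Millero (1995)
kp3,1.586880e-09,8.7995,phosphoric acid third; SWS to total,Millero (1995)
ksi,4.037322e-10,9.3939,silicic acid; SWS to total,Millero (1995)
total_boron,4.157576e-04,3.3812,total boron (mol/kg at S=35),Uppstrom (1974)
total_sulfate,2.823543e-02,1.5492,total sulfate (mol/kg at S=35),Morris & Riley (1966)
total_fluoride,6.832584e-05,4.1654,total fluoride (mol/kg at S=35),Riley (1965)
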