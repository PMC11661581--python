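drug,dose_mg,atorvastatin_equivalent_mg
atorvastatin,10,10
atorvastatin,20,20
atorvastatin,40,40
atorvastatin,80,80
rosuvastatin,5,10
rosuvastatin,10,20
rosuvastatin,20,40
rosuvastatin,40,80
simvastatin,10,5
simvastatin,20,10
simvastatin,40,20
simvastatin,80,40
pravastatin,20,5
pravastatin,40,10
pravastatin,80,20
fluvastatin,40,5
fluvastatin,80,10
lovastatin,20,5
lovastatin,40,10
lovastatin,80,20
pitavastatin,1,5
pitavastatin,2,10
pitavastatin,4,20
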