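name,kind,role,formula,density_g_cm3,density_anhydrous_g_cm3,density_decahydrate_g_cm3,notes
sodium_carbonate,series,candidate,Na2CO3,,2.54,1.44,"natron constituent; anhydrate to decahydrate (natrite to natron)"
nahcolite,solid,candidate,NaHCO3,2.21,,,"sodium bicarbonate"
halite,solid,candidate,NaCl,2.17,,,"sodium chloride"
sodium_sulphate,series,candidate,Na2SO4,,2.664,1.464,"thenardite to mirabilite"
trona,solid,candidate,Na2CO3.NaHCO3.2H2O,2.14,,,"trisodium hydrogendicarbonate dihydrate; midpoint of 2.11-2.17 range"
hydroxyapatite,solid,reference,Ca10(PO4)6(OH)2,1.8,,,"bone mineral; density of measured crocodile cortical bone, not crystal"
water,solid,matrix,H2O,1.0,,,""
balm,solid,matrix,C6H10O5,1.245,,,"generic resinous organic; density set for mu ~0.18 /cm at 146.1 keV"
aluminium,solid,optical,Al,2.699,,,"filter"
copper,solid,optical,Cu,8.96,,,"filter"
molybdenum,solid,optical,Mo,10.22,,,"filter"
luag,solid,optical,Lu3Al5O12,6.73,,,"Lu3Al5O12 scintillator"
ggg,solid,optical,Gd3Ga5O12,7.08,,,"Gd3Ga5O12 scintillator"
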