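taxon,mitigation_unlimited,mitigation_limited,mitigation_none,bau_unlimited,bau_limited,bau_none
Crax fasciolata pinima,59.57,59.57,-73.54,-99.89,-37.08,-80.24
Psophia obscura,-9.45,-97.19,-99.74,-88.22,-99.26,-99.97
Pteroglossus bitorquatus bitorquatus,-13.59,-13.59,-73.20,-100.00,-42.25,-79.74
Piculus paraensis,17.57,-100.00,-100.00,-100.00,-100.00,-100.00
Thamnophilus aethiops incertus,-100.00,-82.07,-85.61,-89.49,-77.26,-81.83
Phlegopsis nigromaculata paraensis,-26.46,-28.02,-58.71,-92.96,-69.67,-93.84
Dendrocincla merula badia,14.95,14.95,-65.66,-99.98,-53.96,-87.56
Dendrexetastes rufigula paraensis,-100.00,-100.00,-100.00,-99.72,-100.00,-100.00
Synallaxis rutilans omissa,-38.48,-37.97,-59.96,-83.76,-72.08,-79.86
Piprites chloris grisescens,-100.00,-100.00,-100.00,-99.10,-100.00,-100.00
Terenotriccus erythrurus hellmayri,-100.00,-100.00,-100.00,-98.18,-100.00,-100.00
Ramphocaenus melanurus austerus,-28.13,-27.96,-58.00,-83.17,-71.59,-80.46
Granatellus pelzelni paraensis,-99.85,-94.07,-99.44,-100.00,-94.13,-94.13
Tangara velia signata,4.79,4.79,-67.45,-100.00,-58.68,-91.73
Lanio cristatus pallidigula,-100.00,-100.00,-100.00,-100.00,-100.00,-100.00
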