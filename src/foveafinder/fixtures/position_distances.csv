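# Published fovea position validation summaries: mean (SD) distance in
# micrometres between automated and expert-annotated fovea positions,
# per disease cohort, overall and per acquisition device.
disease,scope,axis,mean_um,sd_um
bRVO,overall,X,99.48,78.09
bRVO,overall,Y,124.7,100.2
bRVO,overall,abs,159.5,127.0
bRVO,spectralis,X,102.6,82.56
bRVO,spectralis,Y,116.5,96.85
bRVO,spectralis,abs,155.2,127.3
bRVO,cirrus,X,100.4,73.92
bRVO,cirrus,Y,134.5,109.3
bRVO,cirrus,abs,167.9,131.9
bRVO,topcon,X,67.98,67.53
bRVO,topcon,Y,140.6,87.70
bRVO,topcon,abs,156.2,110.6
cRVO,overall,X,102.0,85.28
cRVO,overall,Y,129.7,115.7
cRVO,overall,abs,165.0,143.8
cRVO,spectralis,X,98.78,80.17
cRVO,spectralis,Y,150.9,124.2
cRVO,spectralis,abs,180.4,147.9
cRVO,cirrus,X,99.02,97.05
cRVO,cirrus,Y,79.92,77.53
cRVO,cirrus,abs,127.2,124.2
cRVO,topcon,X,222.7,45.64
cRVO,topcon,Y,140.6,167.5
cRVO,topcon,abs,263.4,173.6
nAMD,overall,X,173.1,225.1
nAMD,overall,Y,157.2,180.4
nAMD,overall,abs,262,262.9
nAMD,spectralis,X,120.3,112.9
nAMD,spectralis,Y,158.6,116.6
nAMD,spectralis,abs,199.0,162.3
nAMD,cirrus,X,121.4,96.16
nAMD,cirrus,Y,83.94,96.72
nAMD,cirrus,abs,147.6,136.4
nAMD,topcon,X,225.5,291.3
nAMD,topcon,Y,185.8,225.6
nAMD,topcon,abs,325.3,339.1
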