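# Published fovea appearance classification confusion matrices for three
# exudative-disease cohorts (branch RVO, central RVO, neovascular AMD).
# Rows: system-assigned class; columns encoded per record: expert
# ground-truth class. Class order NFD, MFD, AFD.
disease,system,truth,count
bRVO,NFD,NFD,30
bRVO,NFD,MFD,2
bRVO,NFD,AFD,5
bRVO,MFD,NFD,0
bRVO,MFD,MFD,6
bRVO,MFD,AFD,3
bRVO,AFD,NFD,2
bRVO,AFD,MFD,0
bRVO,AFD,AFD,26
cRVO,NFD,NFD,21
cRVO,NFD,MFD,1
cRVO,NFD,AFD,5
cRVO,MFD,NFD,0
cRVO,MFD,MFD,14
cRVO,MFD,AFD,1
cRVO,AFD,NFD,1
cRVO,AFD,MFD,0
cRVO,AFD,AFD,33
nAMD,NFD,NFD,53
nAMD,NFD,MFD,8
nAMD,NFD,AFD,0
nAMD,MFD,NFD,2
nAMD,MFD,MFD,10
nAMD,MFD,AFD,0
nAMD,AFD,NFD,0
nAMD,AFD,MFD,0
nAMD,AFD,AFD,7
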