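# reported_confusion v1: published green-plum defect-network test confusion
# rows = true class, columns = predicted class
,rot,spot,scar,crack,normal
rot,794,0,6,0,0
spot,3,744,19,1,33
scar,30,5,236,9,0
crack,17,10,8,125,0
normal,0,16,4,0,440
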