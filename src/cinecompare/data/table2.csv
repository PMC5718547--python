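observer1,observer2,count
recalculated,recalculated,29
recalculated,neither,1
recalculated,original,0
neither,recalculated,8
neither,neither,10
neither,original,0
original,recalculated,1
original,neither,0
original,original,1
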