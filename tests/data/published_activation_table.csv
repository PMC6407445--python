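electrode_model,configuration,activated_contact,percent_activation
3093,Monopolar,0,50
3093,Monopolar,1,35
3093,Monopolar,2,50
3093,Monopolar,3,60
3093,Bipolar,0,50
3093,Bipolar,1,40
3389,Monopolar,0,50
3389,Monopolar,1,50
3389,Monopolar,2,50
3389,Monopolar,3,55
3389,Bipolar,0,50
3389,Bipolar,1,50
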