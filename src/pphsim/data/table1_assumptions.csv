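assumption_id,scenario,minimum,likeliest,maximum,distribution,source
pph_given_use,all,6,12,17,triangle,RCTs
death_given_pph_use,all,0.2,0.3,0.4,triangle,Project data
pph_given_nonuse,all,12,17,22,triangle,RCTs
death_given_pph_nonuse,all,0.2,0.3,0.4,triangle,Project data
cdk_received,project,49,69,89,triangle,Project data
miso_given_cdk,project,80,94,100,triangle,Project data
no_miso_given_cdk,project,0,6,20,triangle,Project data
cdk_received,none,0,0,0,uniform,Set level
miso_given_cdk,none,0,0,0,uniform,Set level
no_miso_given_cdk,none,100,100,100,uniform,Set level
cdk_received,low,20,40,60,triangle,Set level
miso_given_cdk,low,80,94,100,triangle,Project data
no_miso_given_cdk,low,0,6,20,triangle,Project data
cdk_received,high,60,80,100,triangle,Set level
miso_given_cdk,high,80,94,100,triangle,Project data
no_miso_given_cdk,high,0,6,20,triangle,Project data
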