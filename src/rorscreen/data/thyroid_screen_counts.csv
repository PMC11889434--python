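drug,drug_class,reports_with_event,reports_other_events
semaglutide,GLP-1 receptor agonist,124,29401
dulaglutide,GLP-1 receptor agonist,131,65684
liraglutide,GLP-1 receptor agonist,316,36562
tirzepatide,dual GIP/GLP-1 receptor agonist,37,31928
empagliflozin,SGLT-2 inhibitor,11,30778
dapagliflozin,SGLT-2 inhibitor,7,12714
metformin,biguanide,17,53172
phentermine,sympathomimetic,0,1427
naltrexone,opioid receptor antagonist,2,24375
orlistat,lipase inhibitor,4,23841
topiramate,sodium channel blocker / glutamate inhibitor,14,34652
bupropion,norepinephrine-dopamine reuptake inhibitor,0,17692
rosuvastatin,HMG-CoA reductase inhibitor,12,13890
glyburide,sulfonylurea,1,4617
insulin glargine,insulin,63,104510
all_drugs,any,14370,25925016
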