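key,canonical,drug_class
semaglutide,semaglutide,GLP-1 receptor agonist
ozempic,semaglutide,GLP-1 receptor agonist
wegovy,semaglutide,GLP-1 receptor agonist
rybelsus,semaglutide,GLP-1 receptor agonist
dulaglutide,dulaglutide,GLP-1 receptor agonist
trulicity,dulaglutide,GLP-1 receptor agonist
liraglutide,liraglutide,GLP-1 receptor agonist
victoza,liraglutide,GLP-1 receptor agonist
saxenda,liraglutide,GLP-1 receptor agonist
tirzepatide,tirzepatide,dual GIP/GLP-1 receptor agonist
mounjaro,tirzepatide,dual GIP/GLP-1 receptor agonist
monjaro,tirzepatide,dual GIP/GLP-1 receptor agonist
zepbound,tirzepatide,dual GIP/GLP-1 receptor agonist
empagliflozin,empagliflozin,SGLT-2 inhibitor
jardiance,empagliflozin,SGLT-2 inhibitor
dapagliflozin,dapagliflozin,SGLT-2 inhibitor
farxiga,dapagliflozin,SGLT-2 inhibitor
forxiga,dapagliflozin,SGLT-2 inhibitor
canagliflozin,canagliflozin,SGLT-2 inhibitor
invokana,canagliflozin,SGLT-2 inhibitor
metformin,metformin,biguanide
glucophage,metformin,biguanide
sitagliptin,sitagliptin,DPP-4 inhibitor
januvia,sitagliptin,DPP-4 inhibitor
linagliptin,linagliptin,DPP-4 inhibitor
tradjenta,linagliptin,DPP-4 inhibitor
alogliptin,alogliptin,DPP-4 inhibitor
nesina,alogliptin,DPP-4 inhibitor
vildagliptin,vildagliptin,DPP-4 inhibitor
galvus,vildagliptin,DPP-4 inhibitor
saxagliptin,saxagliptin,DPP-4 inhibitor
onglyza,saxagliptin,DPP-4 inhibitor
pioglitazone,pioglitazone,thiazolidinedione
actos,pioglitazone,thiazolidinedione
orlistat,orlistat,lipase inhibitor
xenical,orlistat,lipase inhibitor
alli,orlistat,lipase inhibitor
bupropion,bupropion,norepinephrine-dopamine reuptake inhibitor
wellbutrin,bupropion,norepinephrine-dopamine reuptake inhibitor
zyban,bupropion,norepinephrine-dopamine reuptake inhibitor
topiramate,topiramate,sodium channel blocker / glutamate inhibitor
topamax,topiramate,sodium channel blocker / glutamate inhibitor
phentermine,phentermine,sympathomimetic
adipex,phentermine,sympathomimetic
adipex p,phentermine,sympathomimetic
naltrexone,naltrexone,opioid receptor antagonist
revia,naltrexone,opioid receptor antagonist
vivitrol,naltrexone,opioid receptor antagonist
insulin glargine,insulin glargine,insulin
lantus,insulin glargine,insulin
toujeo,insulin glargine,insulin
basaglar,insulin glargine,insulin
rosuvastatin,rosuvastatin,HMG-CoA reductase inhibitor
crestor,rosuvastatin,HMG-CoA reductase inhibitor
glyburide,glyburide,sulfonylurea
glibenclamide,glyburide,sulfonylurea
diabeta,glyburide,sulfonylurea
micronase,glyburide,sulfonylurea
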