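raw,category
TBI,Traumatic brain injury
"TBI, IS",Traumatic brain injury
TBI (Op),Traumatic brain injury
IS,Ischemic stroke
IS (RA),Ruptured aneurysm
"IS, IVH",Intraventricular hemorrhage
HS,Hemorrhagic stroke
HS (RA),Ruptured aneurysm
Inf,Infection
Anoxia,Anoxia
Other,Other vascular disease
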