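preferred_term,subtype
Thyroid cancer,generic
Thyroid neoplasm,generic
Thyroid cancer recurrent,recurrent
Recurrent thyroid cancer,recurrent
Papillary thyroid cancer,papillary
Follicular thyroid cancer,follicular
Medullary thyroid cancer,medullary
Anaplastic thyroid cancer,anaplastic
Thyroid cancer metastatic,metastatic
Metastatic thyroid cancer,metastatic
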