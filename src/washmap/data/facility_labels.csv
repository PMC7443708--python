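domain,label,category
water,piped on premises,1
water,piped off premises,1
water,piped,1
water,piped into dwelling,1
water,piped to yard,1
water,public tap,1
water,protected well,2
water,protected spring,2
water,bottled water,2
water,rainwater collection,2
water,bought water,2
water,tanker truck,2
water,unprotected well,3
water,unprotected spring,3
water,surface water,4
water,river or stream,4
water,pond or lake,4
sanitation,sewer,1
sanitation,septic tank,1
sanitation,flush to sewer,1
sanitation,flush to septic tank,1
sanitation,improved latrine,2
sanitation,ventilated improved latrine,2
sanitation,pit latrine with slab,2
sanitation,composting toilet,2
sanitation,flush to open channel,3
sanitation,unimproved latrine,3
sanitation,pit latrine without slab,3
sanitation,hanging latrine,3
sanitation,open defecation,4
sanitation,no facility,4
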