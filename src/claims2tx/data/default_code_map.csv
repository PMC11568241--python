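modality,agent,code
chemo,carboplatin,J9045
chemo,cyclophosphamide,J9070
chemo,cyclophosphamide,J9080
chemo,docetaxel,J9170
chemo,docetaxel,J9171
chemo,doxorubicin,J9000
chemo,paclitaxel,J9265
chemo,paclitaxel,J9267
biologic,trastuzumab,J9355
endocrine,tamoxifen,000930782
endocrine,tamoxifen,000930784
endocrine,anastrozole,003100201
endocrine,letrozole,000780249
endocrine,exemestane,000097663
radiotherapy_delivery,,77401
radiotherapy_delivery,,77402
radiotherapy_delivery,,77412
radiotherapy_delivery,,77413
radiotherapy_delivery,,77414
radiotherapy_delivery,,77416
radiotherapy_delivery,,77418
radiotherapy_delivery,,77787
radiotherapy_delivery,,77778
radiotherapy_planning,,77261
radiotherapy_planning,,77262
radiotherapy_planning,,77263
radiotherapy_planning,,77280
radiotherapy_planning,,77285
radiotherapy_planning,,77290
radiotherapy_planning,,77295
radiotherapy_planning,,77300
radiotherapy_planning,,77301
radiotherapy_planning,,77306
radiotherapy_planning,,77307
radiotherapy_planning,,77336
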