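sample,group
LAC_1,LAC
LAC_2,LAC
LAC_3,LAC
LAC_4,LAC
LAC_5,LAC
LAC_6,LAC
LAY_11,LAY
LAY_12,LAY
LAY_15,LAY
LAY_16,LAY
LAY_18,LAY
LAY_19,LAY
LAD_1,LAD
LAD_2,LAD
LAD_3,LAD
LAD_4,LAD
LAD_5,LAD
CHG_27,CHG
CHG_28,CHG
CHG_29,CHG
CHG_30,CHG
CHG_33,CHG
DHC_34,DHC
DHC_35,DHC
DHC_37,DHC
DHC_38,DHC
DHC_39,DHC
ZAP_1,ZAP
ZAP_2,ZAP
ZAP_3,ZAP
ZAP_4,ZAP
ZAP_5,ZAP
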