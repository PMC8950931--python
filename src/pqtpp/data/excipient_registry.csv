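name_pattern,route,min_age_months,max_age_months,adi_mg_per_kg_day,severity,function_discount
benzoic acid|(?<!hydroxy)benzoate,any,0,1,5,known,true
ethanol|\balcohol\b,oral,,,,known,true
propylene glycol,any,,,25,potential,true
paraben|parahydroxybenzoate,any,,,10,potential,false
sorbitol|maltitol|xylitol|mannitol|polyol,oral,,,,potential,false
sucrose|\bsugar\b,oral,,,,potential,false
azo dye|tartrazine|sunset yellow|ponceau|carmoisine|allura red|quinoline yellow|colourant|colorant,oral,,,,potential,false
saccharin,oral,,,,potential,false
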