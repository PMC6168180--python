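scenario,food,instrument,price_response,snap_dollar_share,snap_venue_share,spend_shift
fv_incentive,fruits,incentive,0.34988038,0.76,0.88,0.0
fv_incentive,vegetables,incentive,0.28409091,0.76,0.88,0.0
fv_ssb_restrict,fruits,incentive,0.34988038,0.76,0.88,0.0
fv_ssb_restrict,vegetables,incentive,0.28409091,0.76,0.88,0.0
fv_ssb_restrict,ssb,restriction,-1.0,0.664,1.0,0.5
snap_plus,fruits,incentive,0.34988038,0.76,0.88,0.0
snap_plus,vegetables,incentive,0.31945253,0.76,0.88,0.0
snap_plus,nuts,incentive,0.47071593,0.76,0.88,0.0
snap_plus,whole_grains,incentive,0.36573612,0.76,0.88,0.0
snap_plus,fish,incentive,0.28307474,0.76,0.88,0.0
snap_plus,plant_oils,incentive,0.30384054,0.76,0.88,0.0
snap_plus,ssb,disincentive,-0.26829260,0.76,0.88,0.3
snap_plus,processed_meat,disincentive,-0.34256955,0.76,0.88,0.3
snap_plus,junk_food,disincentive,-0.36938724,0.76,0.88,0.3
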