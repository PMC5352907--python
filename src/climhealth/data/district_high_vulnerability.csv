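county,indicator_id,hazard
Daviess,children,heat
Daviess,children,drought
Daviess,children,flood
Daviess,elderly,heat
Daviess,elderly,drought
Daviess,elderly,flood
Daviess,homeless,heat
Daviess,mental_health,drought
Daviess,mental_health,flood
Daviess,long_term_care,flood
Daviess,fema_floodplain,flood
Hancock,children,heat
Hancock,children,drought
Hancock,children,flood
Hancock,elderly,heat
Hancock,elderly,drought
Hancock,elderly,flood
Hancock,outdoor_workers,heat
Hancock,diabetes,heat
Hancock,diabetes,drought
Hancock,diabetes,flood
Hancock,heart_disease,heat
Hancock,clrd,drought
Hancock,long_term_care,flood
Hancock,fema_floodplain,flood
Henderson,children,heat
Henderson,children,drought
Henderson,children,flood
Henderson,elderly,heat
Henderson,elderly,drought
Henderson,elderly,flood
Henderson,diabetes,heat
Henderson,diabetes,drought
Henderson,diabetes,flood
Henderson,clrd,drought
Henderson,asthma,heat
Henderson,asthma,drought
Henderson,cerebrovascular_disease,heat
Henderson,fema_floodplain,flood
Henderson,stressed_housing,heat
Henderson,stressed_housing,drought
Henderson,stressed_housing,flood
McLean,children,heat
McLean,children,drought
McLean,children,flood
McLean,elderly,heat
McLean,elderly,drought
McLean,elderly,flood
McLean,outdoor_workers,heat
McLean,diabetes,heat
McLean,diabetes,drought
McLean,diabetes,flood
McLean,heart_disease,heat
McLean,cerebrovascular_disease,heat
McLean,long_term_care,flood
McLean,fema_floodplain,flood
Ohio,children,heat
Ohio,children,drought
Ohio,children,flood
Ohio,elderly,heat
Ohio,elderly,drought
Ohio,elderly,flood
Ohio,poverty,heat
Ohio,poverty,drought
Ohio,poverty,flood
Ohio,outdoor_workers,heat
Ohio,diabetes,heat
Ohio,diabetes,drought
Ohio,diabetes,flood
Ohio,heart_disease,heat
Ohio,long_term_care,flood
Ohio,fema_floodplain,flood
Union,elderly,heat
Union,elderly,drought
Union,elderly,flood
Union,outdoor_workers,heat
Union,obesity,heat
Union,heart_disease,heat
Union,cerebrovascular_disease,heat
Union,fema_floodplain,flood
Webster,elderly,heat
Webster,elderly,drought
Webster,elderly,flood
Webster,outdoor_workers,heat
Webster,obesity,heat
Webster,diabetes,heat
Webster,diabetes,drought
Webster,diabetes,flood
Webster,heart_disease,heat
Webster,clrd,drought
Webster,asthma,heat
Webster,asthma,drought
Webster,cerebrovascular_disease,heat
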