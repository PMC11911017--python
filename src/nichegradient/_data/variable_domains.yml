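# Default variable-domain registry for the 16 environmental gradients of the
# tree-species study.  "lower"/"upper" of null means unbounded on that side.
# Eleven variables are nonnegative, the summer/total precipitation ratio lives
# on [0, 1], and the four temperature variables plus soil pH are treated as
# unbounded (pH is chemically bounded, but it is analysed as untruncated).
variables:
  annual_dryness_index: {lower: 0, upper: null}
  terrain_slope: {lower: 0, upper: null}
  cation_exchange_capacity: {lower: 0, upper: null}
  elevation: {lower: 0, upper: null}
  mean_annual_precipitation: {lower: 0, upper: null}
  mean_annual_temperature: {lower: null, upper: null}
  coldest_month_temperature: {lower: null, upper: null}
  warmest_month_temperature: {lower: null, upper: null}
  summer_total_precipitation_ratio: {lower: 0, upper: 1}
  soil_organic_carbon: {lower: 0, upper: null}
  soil_ph: {lower: null, upper: null}
  spring_precipitation: {lower: 0, upper: null}
  summer_precipitation: {lower: 0, upper: null}
  summer_precipitation_balance: {lower: 0, upper: null}
  summer_spring_precipitation_balance: {lower: 0, upper: null}
  winter_precipitation: {lower: 0, upper: null}

# Editable alias table mapping spreadsheet-style headers to canonical labels.
aliases:
  "Annual dryness index": annual_dryness_index
  "Average slope of the terrain (deg)": terrain_slope
  "Cation exchange capacity of soil (cmolc/kg)": cation_exchange_capacity
  "Elevation above sea level (m)": elevation
  "Mean annual precipitation (mm)": mean_annual_precipitation
  "Mean annual temperature (C)": mean_annual_temperature
  "Mean temperature in the coldest month (C)": coldest_month_temperature
  "Mean temperature in the warmest month (C)": warmest_month_temperature
  "Ratio of summer to total precipitation": summer_total_precipitation_ratio
  "Soil organic-carbon content (g/kg)": soil_organic_carbon
  "Soil's pH value": soil_ph
  "Spring precipitation (mm)": spring_precipitation
  "Summer precipitation (mm)": summer_precipitation
  "Summer precipitation balance": summer_precipitation_balance
  "Summer/spring precipitation-balance": summer_spring_precipitation_balance
  "Winter precipitation (mm)": winter_precipitation
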