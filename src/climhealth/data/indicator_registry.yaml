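# Default indicator registry for the seven-county district assessment:
# environmental exposure, health outcome, population vulnerability, and
# environmental vulnerability indicators, each mapped to the climate
# hazards (heat / drought / flood) it informs and to a worse-direction.
#
# Five indicators carry a federal standard or goal (EPA annual
# fine-particulate standard; Healthy People 2020 goals NWS-9, HDS-2,
# RD-2.2, HDS-3).  The standard *values* are deliberately null here: they
# are required configuration entries, and comparing against an unset
# standard raises a configuration error.
indicators:
  # --- environmental exposure -------------------------------------------
  - id: heat_wave_exposure
    name: Exposure to heat waves
    category: environmental_exposure
    hazards: [heat]
    direction: higher_is_worse
  - id: heavy_precipitation_days
    name: Exposure to heavy precipitation events
    category: environmental_exposure
    hazards: [flood]
    direction: higher_is_worse
  - id: air_pollution_pm25
    name: Exposure to air pollution (annual mean PM2.5, ug/m3)
    category: environmental_exposure
    hazards: [drought]
    direction: higher_is_worse
    standard:
      source: US EPA 2012 annual fine particulate matter standard
      value: null
  - id: drought_exposure
    name: Exposure to drought (weeks at D2 or worse)
    category: environmental_exposure
    hazards: [drought]
    direction: higher_is_worse
  # --- human health outcome ---------------------------------------------
  - id: heat_mortality
    name: Heat-related mortality during extreme heat events
    category: health_outcome
    hazards: [heat]
    direction: higher_is_worse
  - id: heat_morbidity
    name: Heat-related morbidity during extreme heat events
    category: health_outcome
    hazards: [heat]
    direction: higher_is_worse
  - id: flood_mortality
    name: Unintentional flooding-related mortality
    category: health_outcome
    hazards: [flood]
    direction: higher_is_worse
  - id: flood_morbidity
    name: Unintentional flooding-related morbidity
    category: health_outcome
    hazards: [flood]
    direction: higher_is_worse
  # --- population vulnerability -----------------------------------------
  - id: children
    name: Children (share of population)
    category: population_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
  - id: elderly
    name: Elderly aged 65+ (share of population)
    category: population_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
  - id: poverty
    name: Population living in poverty
    category: population_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
  - id: non_hispanic_black
    name: Non-Hispanic Black population share
    category: population_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
  - id: outdoor_workers
    name: Outdoor workers (share of workforce)
    category: population_vulnerability
    hazards: [heat]
    direction: higher_is_worse
  - id: limited_english
    name: Population with limited English proficiency
    category: population_vulnerability
    hazards: [flood]
    direction: higher_is_worse
  - id: ambulatory_difficulty
    name: Population with ambulatory difficulty
    category: population_vulnerability
    hazards: [flood]
    direction: higher_is_worse
  - id: homeless
    name: Homeless population rate
    category: population_vulnerability
    hazards: [heat]
    direction: higher_is_worse
  - id: long_term_care
    name: Patients in long-term care facilities
    category: population_vulnerability
    hazards: [flood]
    direction: higher_is_worse
  - id: diabetes
    name: Diabetes prevalence
    category: population_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
  - id: heart_disease
    name: Heart disease mortality
    category: population_vulnerability
    hazards: [heat]
    direction: higher_is_worse
    standard:
      source: Healthy People 2020 Goal HDS-2
      value: null
  - id: cerebrovascular_disease
    name: Cerebrovascular disease deaths
    category: population_vulnerability
    hazards: [heat]
    direction: higher_is_worse
    standard:
      source: Healthy People 2020 Goal HDS-3
      value: null
  - id: clrd
    name: Chronic lower respiratory disease prevalence
    category: population_vulnerability
    hazards: [drought]
    direction: higher_is_worse
  - id: asthma
    name: Asthma hospitalizations
    category: population_vulnerability
    hazards: [heat, drought]
    direction: higher_is_worse
    standard:
      source: Healthy People 2020 Goal RD-2.2
      value: null
  - id: obesity
    name: Obesity prevalence
    category: population_vulnerability
    hazards: [heat]
    direction: higher_is_worse
    standard:
      source: Healthy People 2020 Goal NWS-9
      value: null
  - id: mental_health
    name: Population requiring mental health services
    category: population_vulnerability
    hazards: [drought, flood]
    direction: higher_is_worse
  # --- environmental vulnerability --------------------------------------
  - id: fema_floodplain
    name: Population living in the FEMA 100-year floodplain
    category: environmental_vulnerability
    hazards: [flood]
    direction: higher_is_worse
  - id: carbon_monoxide_poisoning
    name: Carbon monoxide poisoning ED visits
    category: environmental_vulnerability
    hazards: [heat, flood]
    direction: higher_is_worse
  - id: air_conditioning_access
    name: Household air conditioning access
    category: environmental_vulnerability
    hazards: [heat]
    direction: lower_is_worse
  - id: stressed_housing
    name: Stressed housing rate
    category: environmental_vulnerability
    hazards: [heat, drought, flood]
    direction: higher_is_worse
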