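study_label,cause,region,period,deaths_central,deaths_lower,deaths_upper,bound_kind,deaths_basis,estimate_type,collection,notes
Carlson et al.,Malaria,sub-Saharan Africa,2010-2015,2366.0,-4925.0,19423.0,ci95,annual,attribution,core_attribution,period as printed; source prevalence estimate covers 2010-2014
Newman and Noy,Extreme weather (excluding heat waves),global,2000-2019,2560.0,,,,annual,attribution,core_attribution,no interval published
Childs et al.,Dengue fever,global,1995-2014,3925.0,1915.0,7028.0,ci95,annual,attribution,core_attribution,
Vicedo-Cabrera et al.,Heat,43 countries,1991-2018,9702.0,4005.0,19135.0,ci95,annual,attribution,core_attribution,
Park et al.,Fire-related air pollution mortality,global,2010-2019,12566.0,3481.0,30126.0,range,annual,attribution,core_attribution,
McMichael et al.,Floods,global,2000-2000,2000.0,,,,annual,projection,mcmichael_2000,
McMichael et al.,Heat,global,2000-2000,12000.0,,,,annual,projection,mcmichael_2000,
McMichael et al.,Malaria,global,2000-2000,27000.0,,,,annual,projection,mcmichael_2000,
McMichael et al.,Diarrhoeal disease,global,2000-2000,47000.0,,,,annual,projection,mcmichael_2000,
McMichael et al.,Malnutrition,global,2000-2000,77000.0,,,,annual,projection,mcmichael_2000,
Hales et al.,Dengue fever,global,2030-2030,258.0,136.0,331.0,range,annual,projection,hales_2030,
Hales et al.,Heat (>65 years old),global,2030-2030,37588.0,26912.0,48390.0,range,annual,projection,hales_2030,
Hales et al.,Diarrhoeal disease (<15 years old),global,2030-2030,48114.0,21097.0,67702.0,range,annual,projection,hales_2030,
Hales et al.,Malaria,global,2030-2030,60091.0,37608.0,117001.0,range,annual,projection,hales_2030,
Hales et al.,Undernutrition (<5 years old),global,2030-2030,95176.0,-119807.0,310156.0,range,annual,projection,hales_2030,
Vicedo-Cabrera et al.,Heat,43 countries,1991-2018,271656.0,,,,cumulative,attribution,supplementary,cumulative toll underlying the annual heat record
Temperature-related neonatal deaths,Neonatal deaths,29 low- and middle-income countries,,9218.75,,,,annual,attribution,supplementary,"implied count: US$29.5e9 adjusted loss / US$3.2e6 reported VSL; deaths not published, excluded from exact reproduction"
Chevron,Heat (source attribution),Zurich,1969-2018,59.0,,,,cumulative,attribution,emitters,
ExxonMobil,Heat (source attribution),Zurich,1969-2018,54.0,,,,cumulative,attribution,emitters,
Saudi Aramco,Heat (source attribution),Zurich,1969-2018,53.0,,,,cumulative,attribution,emitters,
London 2006 heat wave,Heat,London,2006-2006,10.0,,,,cumulative,attribution,community,single day of the 2006 heat wave; partial community-level set
Zurich 1969-2018,Heat,Zurich,1969-2018,1683.0,,,,cumulative,attribution,community,partial community-level set
Switzerland 2022 heat wave,Heat,Switzerland,2022-2022,370.0,,,,cumulative,attribution,community,partial community-level set
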