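name,group,kind,units,description
Bio1,climatic,continuous,degC,Annual mean temperature
Bio2,climatic,continuous,degC,Mean diurnal range (mean of monthly max temp minus mean of monthly min temp)
Bio3,climatic,continuous,degC,Isothermality (Bio2/Bio7 x 100)
Bio4,climatic,continuous,degC,Temperature seasonality (standard deviation x 100)
Bio5,climatic,continuous,degC,Max temperature of warmest month
Bio6,climatic,continuous,degC,Min temperature of coldest month
Bio7,climatic,continuous,degC,Temperature annual range (Bio5-Bio6)
Bio8,climatic,continuous,degC,Mean temperature of wettest quarter
Bio9,climatic,continuous,degC,Mean temperature of driest quarter
Bio10,climatic,continuous,degC,Mean temperature of warmest quarter
Bio11,climatic,continuous,degC,Mean temperature of coldest quarter
Bio12,climatic,continuous,mm/m2,Annual precipitation
Bio13,climatic,continuous,mm/m2,Precipitation of wettest month
Bio14,climatic,continuous,mm/m2,Precipitation of driest month
Bio15,climatic,continuous,mm/m2,Precipitation seasonality (coefficient of variation)
Bio16,climatic,continuous,mm/m2,Precipitation of wettest quarter
Bio17,climatic,continuous,mm/m2,Precipitation of driest quarter
Bio18,climatic,continuous,mm/m2,Precipitation of warmest quarter
Bio19,climatic,continuous,mm/m2,Precipitation of coldest quarter
WatVapPress01,climatic,continuous,kPa,Water vapour pressure of the wettest month (source table prints the same label for both months)
WatVapPress02,climatic,continuous,kPa,Water vapour pressure of the driest month (source table prints the same label for both months)
Elevation,climatic,continuous,m.a.s.l,Metres above sea level
Soil_pH,soil,continuous,pH x10 in H2O,Soil pH
Soil_CatEx_Capacity,soil,continuous,cmole/kg at depth 0.00 m,Soil cation exchange capacity
Soil_Bulk_D,soil,continuous,kg/m3 at depth 0.00 m,Soil bulk density
Soil_Organic_Carbon,soil,continuous,g/kg at depth 0.00 m,Soil organic carbon
Soil_Clay,soil,continuous,mass fraction % at depth 0.00 m,Soil clay content
Soil_Silt,soil,continuous,mass fraction % at depth 0.00 m,Soil silt content
Soil_Sand,soil,continuous,mass fraction % at depth 0.00 m,Soil sand content
Soil_Water_Capacity,soil,continuous,mm2/1 m soil depth,Soil total available water capacity
Forest,vegetation_landcover,continuous,%,Forest cover
Grass_Land,vegetation_landcover,continuous,%,Grass/shrub land
Cult_L,vegetation_landcover,continuous,%,Land used for agricultural purposes (cultivated land)
Crop_Dominance,vegetation_landcover,categorical,category,Crop dominance (major crops)
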