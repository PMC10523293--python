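resource_id,name,aliases,line1,city,state,zip,roles
R001,Hope House,Hope House Shelter,201 Compassion Way,Lexington,KY,40508,emergency_shelter|transitional_housing
R002,New Start,New Start Center,455 Recovery Road,Lexington,KY,40505,emergency_shelter
R003,Harbor Light Mission,Harbor Light,820 Industry Ave,Lexington,KY,40511,emergency_shelter
R004,Safe Haven Shelter,Safe Haven,77 Winchester Pike,Lexington,KY,40509,emergency_shelter|transitional_housing
R005,Phoenix Recovery Residence,Phoenix Recovery,1310 Meadow Ln,Lexington,KY,40517,residential_sud_treatment
R006,Bluegrass Transitional Housing,Bluegrass House,96 Limestone St,Lexington,KY,40507,transitional_housing
R007,Open Door Emergency Shelter,Open Door,640 Manchester St,Lexington,KY,40504,emergency_shelter
R008,Riverbend Recovery Center,Riverbend Center,2200 Palumbo Dr,Lexington,KY,40502,residential_sud_treatment
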