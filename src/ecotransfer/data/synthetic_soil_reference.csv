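# SYNTHETIC soil-reference table for demonstrations and tests.
# The two Cs137 rows use literature massic activities (109 and 141 Bq/kg dry
# mass); their reference dates are placeholders (mid-years of plausible survey
# windows) because the sources' reference dates are not published. The Pb210
# and stable-element rows are invented, order-of-magnitude-plausible values.
analyte,value,unit,basis,reference_date,source
Cs137,109,Bq/kg,dry,2013-07-01,literature value A (reference date placeholder)
Cs137,141,Bq/kg,dry,2015-07-01,literature value B (reference date placeholder)
Pb210,34,Bq/kg,dry,2015-07-01,synthetic placeholder
Cd,0.9,mg/kg,dry,,synthetic placeholder
Pb,40,mg/kg,dry,,synthetic placeholder
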