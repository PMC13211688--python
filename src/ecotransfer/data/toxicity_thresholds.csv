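# Literature screening thresholds for stable elements in carnivore tissues.
# Values in mg/kg; entries with a dry_mass_factor_applied are published on a
# wet-mass basis and are multiplied by that (wet-to-dry) tissue factor before
# comparison against dry-mass measurements. Band entries carry threshold_high.
analyte,tissue,threshold_value,threshold_high,threshold_kind,dry_mass_factor_applied,source
As,liver,10,,toxic,3.03,canine reference levels
As,kidney,10,,toxic,4,canine reference levels
Ca,liver,100,757,adequate,,canine reference levels
Ca,kidney,2000,,high,,canine reference levels
Cd,liver,3.03,21.2,high,,canine reference levels
Cd,kidney,120,,toxic,,terrestrial mammal toxicity literature
Cu,liver,1212,,toxic,,canine reference levels
Cu,kidney,80,,toxic,,canine reference levels
Fe,liver,424,,adequate,,canine reference levels
Fe,kidney,560,,adequate,,canine reference levels
Hg,liver,91,,toxic,,terrestrial mammal toxicity literature
Hg,kidney,120,,toxic,,terrestrial mammal toxicity literature
Mn,liver,9.09,15.1,adequate,,canine reference levels
Mn,kidney,4.8,7.2,adequate,,canine reference levels
Pb,liver,25,30,toxic,,terrestrial mammal toxicity literature
Pb,kidney,15,,toxic,,terrestrial mammal toxicity literature
Pb,bone,25,,toxic,,terrestrial mammal toxicity literature
Se,liver,20,,toxic,,terrestrial mammal toxicity literature
Se,kidney,4,6,adequate,,canine reference levels
Tl,liver,23.0,,toxic,,canine reference levels
Tl,kidney,136,,toxic,,canine reference levels
U,kidney,4,9.2,toxic,,canine reference levels
V,liver,0.09,0.182,adequate,,canine reference levels
V,kidney,0.12,0.2,adequate,,canine reference levels
Zn,liver,1118,,toxic,,canine reference levels
Zn,kidney,1180,,toxic,,canine reference levels
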