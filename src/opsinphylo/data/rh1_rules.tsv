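# Rod opsin (RH1) three-site spectral tuning rule: residues at bovine-numbering
# sites 83, 292, 299 -> lambda_max (nm) from expressed-pigment measurements.
# value "unknown" means the combination has not been measured.
opsin	sites	tuple	lambda_low	lambda_high	provenance
RH1	83,292,299	DAS	501	501	bovine wild-type pigment
RH1	83,292,299	NSS	484	484	expressed mutant pigment
RH1	83,292,299	NSA	479	479	expressed mutant pigment
RH1	83,292,299	NAS	493	493	expressed mutant pigment
RH1	83,292,299	DSS	492	492	expressed mutant pigment
RH1	83,292,299	NAT	unknown	unknown	no measurement for T at 299
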