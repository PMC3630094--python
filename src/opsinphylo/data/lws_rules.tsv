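# L-cone opsin (LWS) five-sites spectral tuning rule: residues at sites
# 180, 197, 277, 285, 308 -> lambda_max (nm); ranges reflect measurement spread.
opsin	sites	tuple	lambda_low	lambda_high	provenance
LWS	180,197,277,285,308	AHYTA	552	552	expressed pigment
LWS	180,197,277,285,308	AHYTS	522	531	expressed pigments, range across measurements
LWS	180,197,277,285,308	AHYTP	unknown	unknown	effect of P at 308 unmeasured
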