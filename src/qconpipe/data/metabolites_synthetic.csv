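# SYNTHETIC metabolite concentration table for testing the occupancy stage.
# GAP, E4P and Ru5P are back-computed from published substrate-per-binding-site
# fold ratios; all other values are plausible invented placeholders.
metabolite,um
RuBP,600.0
3PGA,2500.0
BPGA,8.0
GAP,32.6
DHAP,90.0
FBP,150.0
F6P,350.0
E4P,40.0
SBP,920.0
S7P,600.0
X5P,35.0
R5P,25.0
Ru5P,56.3
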