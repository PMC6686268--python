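# Curated cis-regulatory element consensus table (IUPAC), approximating the
# commonly cited PlantCARE stress/hormone/light elements.  Users may supply
# their own TSV with the same columns; counts depend on the table chosen.
name	consensus	category
ABRE	ACGTG	hormone_ABA
ARE	AAACCA	stress_anaerobic
G-box	CACGTG	light
CGTCA-motif	CGTCA	hormone_MeJA
LTR	CCGAAA	stress_cold
MBS	CAACTG	stress_drought
TCA-element	CCATCTTTTT	hormone_SA
TC-rich_repeats	ATTTTCTTCA	stress_defense
TGA-element	AACGAC	hormone_auxin
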