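# Built-in molecular-function definitions (multi-step stubs over KEGG orthologs).
# Columns: function_id, name, definition.
# Definition grammar: whitespace separates steps; within a step ',' = OR,
# '+' = AND (binds tighter), parentheses group.
function_id	name	definition
nitrogen_fixation	Nitrogen fixation (nitrogenase MoFe + reductase)	K02586+K02591 K02588
photosystem_II	Photosystem II core complex	K02703 K02706 K02704 K02705
fe_mn_transporter	Fe-Mn transporter (MntH-type)	K03322
glucoamylase	Glucoamylase	K01178
chitinase	Chitinase	K01183
riboflavin_biosynthesis	Riboflavin biosynthesis	K14652 K11752 K00794 K00793
chemotaxis	Chemotaxis signal transduction	K03407+K03408 K03412,K00575 K03413
type_I_secretion	Type I secretion system	K12340 K11003+K11004
sec_srp	Sec-SRP secretion pathway	K03070 K03076+K03073 K03106 K03110
glucogenesis	Glucogenesis (fructose-1,6-bisphosphatase route)	K03841,K02446 K01689 K01834,K15633
zeaxanthin_diglucoside	Zeaxanthin diglucoside production	K09844 K09845+K09846
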