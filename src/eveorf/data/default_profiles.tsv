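# Synthetic consensus-peptide profile definitions shipped with eveorf.
# These peptides are INVENTED stand-ins so the built-in matcher and the
# simulator are self-contained; they are NOT authoritative viral motifs.
# Columns: name<TAB>source<TAB>category<TAB>consensus peptide
Gag_p30	pfam	gag	WQPLTHEVKGPGLRAQNDYTAFIVQ
Gag_p24	pfam	gag	NPTEMLQVGDRSHKAYWFICTLPEG
RVP	pfam	pro	DTGADVTILSERWPKNFEIQGAHYM
RVT_1	pfam	pol	YVDDLLLAAHSEKGQTRIWNPMFCE
rve	pfam	pol	GHIEGWKARQTVLDNSPYMFCATEL
RNase_H	gypsy	pol	TDSQYAFGVLRNEWKHIPMCESTLQ
TLV_coat	pfam	env	CKDFNLSRWQAGHMTYIVPELSGDN
Env_gp36	gypsy	env	GLNDWQRIAVESTYHKFMPCDLTEA
DUF_misc	custom	other	QTAYRLWENGKSVHDIPMFCSLQGE
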