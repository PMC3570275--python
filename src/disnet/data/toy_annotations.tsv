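# Annotation fixture for the angiogenin neighborhood worked example.
ANG	function	angiogenesis
ANG	function	vasculature development
RNH1	function	regulation of angiogenesis
ACTC1	function	cardiac muscle development
TDGF1	function	cardiac muscle development
PTEN	function	cardiac muscle development
TDGF1	function	vasculature development
PTEN	function	vasculature development
TDGF1	function	apoptosis
PTEN	function	apoptosis
ACTN2	function	apoptosis
TNFSF8	function	apoptosis
ATP6AP1	function	apoptosis
ANG	phenotype	amyotrophic lateral sclerosis
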