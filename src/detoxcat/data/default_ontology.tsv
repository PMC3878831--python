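pattern	category	family	subfamily
\bcyp4	oxidation_reduction	cytochrome P450	CYP4
\bcyp6	oxidation_reduction	cytochrome P450	CYP6
cytochrome\s*p[- ]?450|\bcyp\d	oxidation_reduction	cytochrome P450
aldehyde dehydrogenase	oxidation_reduction	aldehyde dehydrogenase
alcohol dehydrogenase	oxidation_reduction	alcohol dehydrogenase
catalase	oxidation_reduction	catalase
dehalogenase	oxidation_reduction	dehalogenase
hydroxylase	oxidation_reduction	hydroxylase
oxidoreductase	oxidation_reduction	oxidoreductase
peroxidase	oxidation_reduction	peroxidase
superoxide dismutase	oxidation_reduction	superoxide dismutase
thioredoxin|glutaredoxin	oxidation_reduction	thioredoxin/glutaredoxin
sigma[- ]?class glutathione|glutathione s-transferase sigma|sigma[- ]?gst|\bgsts\d	conjugation	glutathione S-transferase	sigma-GST
epsilon[- ]?class glutathione|glutathione s-transferase epsilon|epsilon[- ]?gst|\bgste\d	conjugation	glutathione S-transferase	epsilon-GST
glutathione s[- ]?transferase|\bgst\b	conjugation	glutathione S-transferase
udp[- ]?glucuronosyltransferase	conjugation	UDP-glucuronosyltransferase
acetyltransferase	conjugation	acetyltransferase
acyltransferase	conjugation	acyltransferase
coa[- ]transferase	conjugation	CoA transferase
formyltransferase	conjugation	formyltransferase
glycosyltransferase	conjugation	glycosyltransferase
methyltransferase	conjugation	methyltransferase
phosphotransferase	conjugation	phosphotransferase
sulfotransferase	conjugation	sulfotransferase
transaminase|aminotransferase	conjugation	transaminase
acetylcholinesterase|carboxyl\s?esterase|\besterase	hydrolysis	carboxylesterase/esterase
(acid|alkaline) phosphatase	hydrolysis	acid/alkaline phosphatase
amidase	hydrolysis	amidase
aminopeptidase	hydrolysis	aminopeptidase
cyclohydrolase	hydrolysis	cyclohydrolase
amylase	hydrolysis	amylase
glucuronidase	hydrolysis	glucuronidase
glucosidase|glycosidase	hydrolysis	glycosidase
glycosylase	hydrolysis	glycosylase
nitrilase	hydrolysis	nitrilase
phosphodiesterase	hydrolysis	phosphodiesterase
phosphohydrolase	hydrolysis	phosphohydrolase
abc transporter|atp[- ]binding cassette	other	ABC transporter
cadherin	other	cadherin
heat[- ]?shock protein|\bhsp\d	other	heat shock protein
isomerase	other	isomerase
\blyase	other	lyase
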