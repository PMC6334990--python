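# tag	class  (content = nominal/verbal/adjectival/adverbial; function = closed-class)
NN	content
NNS	content
NNP	content
NNPS	content
JJ	content
JJR	content
JJS	content
RB	content
RBR	content
RBS	content
VB	content
VBD	content
VBG	content
VBN	content
VBP	content
VBZ	content
CD	content
FW	content
UH	content
PRP	function
PRP$	function
DT	function
MD	function
IN	function
TO	function
CC	function
EX	function
WDT	function
WP	function
WP$	function
WRB	function
RP	function
PDT	function
POS	function
SYM	function
LS	function
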