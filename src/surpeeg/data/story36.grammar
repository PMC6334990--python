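# Synthetic 36-tag story grammar: un-lexicalized PCFG over Penn-Treebank-style
# POS terminals.  Clauses carry a singular/plural register: the head noun
# (NN vs NNS) selects the agreeing finite verb form (VBZ vs VBP) across
# arbitrarily long intervening modifiers (PPs, relative clauses), so the
# grammar's hierarchical state carries predictive information that neither a
# trigram window nor a recency-biased sequence model can fully recover.
# Format: LHS -> RHS1 RHS2 ... PROB   (first rule's lhs is the start symbol)
S -> CL 0.34
S -> CL CC CL 0.62
S -> UH CL 0.04
CL -> CLS 0.5
CL -> CLP 0.5
CLS -> NPS VPS 0.92
CLS -> EX VBZ NPX 0.05
CLS -> VPS 0.03
CLP -> NPP VPP 0.92
CLP -> EX VBP NPX 0.05
CLP -> VPP 0.03
NPX -> NPS 0.5
NPX -> NPP 0.5
NPS -> DETP NOMS 0.29
NPS -> NOMS 0.10
NPS -> PRP 0.16
NPS -> NNP 0.07
NPS -> NPS PP 0.26
NPS -> NPS SBARS 0.12
NPP -> DETP NOMP 0.29
NPP -> NOMP 0.10
NPP -> PRP 0.16
NPP -> NNPS 0.07
NPP -> NPP PP 0.26
NPP -> NPP SBARP 0.12
DETP -> DT 0.85
DETP -> PRP$ 0.08
DETP -> PDT DT 0.03
DETP -> NNP POS 0.04
NOMS -> NN 0.62
NOMS -> ADJP NOMS 0.24
NOMS -> NN NN 0.04
NOMS -> CD NOMS 0.02
NOMS -> FW 0.03
NOMS -> SYM 0.03
NOMS -> LS 0.02
NOMP -> NNS 0.64
NOMP -> ADJP NOMP 0.24
NOMP -> NN NNS 0.04
NOMP -> CD NOMP 0.05
NOMP -> FW 0.03
ADJP -> JJ 0.58
ADJP -> JJR 0.08
ADJP -> JJS 0.05
ADJP -> RB JJ 0.12
ADJP -> VBG 0.09
ADJP -> VBN 0.08
VS -> VBZ 0.72
VS -> VBD 0.28
VPL -> VBP 0.72
VPL -> VBD 0.28
VPS -> VS NPX 0.28
VPS -> VS 0.06
VPS -> VS PP 0.08
VPS -> VS SBARC 0.13
VPS -> MD VB 0.05
VPS -> MD VB NPX 0.05
VPS -> VS TO VB 0.05
VPS -> VPS PP 0.15
VPS -> VS RP 0.04
VPS -> VS ADVP 0.06
VPS -> VS ADJP 0.05
VPP -> VPL NPX 0.28
VPP -> VPL 0.06
VPP -> VPL PP 0.08
VPP -> VPL SBARC 0.13
VPP -> MD VB 0.05
VPP -> MD VB NPX 0.05
VPP -> VPL TO VB 0.05
VPP -> VPP PP 0.15
VPP -> VPL RP 0.04
VPP -> VPL ADVP 0.06
VPP -> VPL ADJP 0.05
ADVP -> RB 0.80
ADVP -> RBR 0.12
ADVP -> RBS 0.08
PP -> IN NPX 0.85
PP -> TO NPX 0.15
SBARS -> WDT VPS 0.55
SBARS -> WP VPS 0.25
SBARS -> WP$ NOMS VPS 0.05
SBARS -> WRB CL 0.15
SBARP -> WDT VPP 0.55
SBARP -> WP VPP 0.25
SBARP -> WP$ NOMP VPP 0.05
SBARP -> WRB CL 0.15
SBARC -> IN CL 0.70
SBARC -> WRB CL 0.30
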