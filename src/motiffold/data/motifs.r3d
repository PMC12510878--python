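# Bundled R3D motif descriptor library.
#
# Format: one record per line, `CLASS NAME key=value ...`; `#` starts a
# comment; an empty value (`L1=`) is an empty segment that can still absorb
# insertions; an absent key means the segment does not exist.
#
# Only motifs whose consensus is spelled out in the primary literature are
# bundled with exact strings (GNRA, U-turn, K-turn right strand, loop E
# branch lengths, the group II J3).  The remaining consensus strings are
# curator choices consistent with published motif descriptions; adjust or
# extend freely -- the folding tool accepts any descriptor file via
# --r3dfile.

# --- hairpin loop motifs -------------------------------------------------
HL GNRA    L1=G Loop=N R1=RA
HL UNCG    L1=U Loop=NC R1=G
HL U-turn  L1= Loop=URA R1=

# --- internal loop motifs ------------------------------------------------
# K-turn: two G.A/A.G sugar-Hoogsteen pairs next to the non-canonical stem,
# a three-nucleotide RNN bulge on the 3' strand, 5' strand otherwise empty.
IL K-turn  Lo= Loop1= Li=GA Ri=GA Loop2=RNN Ro=
# loop E (sarcin/ricin-like): five consensus positions on each branch.
IL loopE   Lo=AGUAU Loop1= Li= Ri=GAURA Loop2= Ro=
IL C-loop  Lo=CAC Loop1= Li= Ri=ACAG Loop2= Ro=

# --- junction motifs -----------------------------------------------------
# hammerhead-style three-way junction: conserved CUGA / GA boxes.
J3 hammerhead S1=CUGANGA S2=GAAA S3=
# group II intron three-way junction: branches A / RAA / empty, the third
# helix reduced to a lone pair with coaxial stacking.
J3 groupII S1=A S2=RAA S3=
# generic four-way junction with coaxially stacked helices (empty branches).
J4 coaxial S1= S2= S3= S4=

# --- branch segment motifs -----------------------------------------------
# CsrA protein-binding motif (GGA core) on any multiloop branch.
BS CsrA    S1=AGGA
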