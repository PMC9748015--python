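# Synthetic default pairwise contact-energy table (simulation units, kB = 1).
# This matrix is a constructed stand-in, NOT a fitted model: it encodes the
# published qualitative constraints for PLCDs -- the sticker hierarchy
# |e_YY| > |e_YF| > |e_FF| > |e_R-aromatic|, aromatics as primary stickers,
# arginine as auxiliary sticker, lysine nearly inert -- and a Y-Y -> Y-K swap
# gap of 18.95 energy units (0.47 kBT at T=40, 0.32 kBT at T=60).
	Y	F	R	K	G	S	T	Q	N	X
Y	-19.2	-17.4	-13.0	-0.25	-5.0	-5.0	-5.0	-5.5	-5.5	-5.0
F	-17.4	-15.6	-13.0	-0.40	-4.5	-4.5	-4.5	-5.0	-5.0	-4.5
R	-13.0	-13.0	-1.0	-0.50	-3.0	-3.0	-3.0	-3.5	-3.5	-3.0
K	-0.25	-0.40	-0.50	-0.30	-1.5	-1.5	-1.5	-1.5	-1.5	-1.5
G	-5.0	-4.5	-3.0	-1.5	-2.5	-2.5	-2.5	-2.8	-2.8	-2.5
S	-5.0	-4.5	-3.0	-1.5	-2.5	-2.5	-2.5	-2.8	-2.8	-2.5
T	-5.0	-4.5	-3.0	-1.5	-2.5	-2.5	-2.5	-2.8	-2.8	-2.5
Q	-5.5	-5.0	-3.5	-1.5	-2.8	-2.8	-2.8	-3.0	-3.0	-2.8
N	-5.5	-5.0	-3.5	-1.5	-2.8	-2.8	-2.8	-3.0	-3.0	-2.8
X	-5.0	-4.5	-3.0	-1.5	-2.5	-2.5	-2.5	-2.8	-2.8	-2.5
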