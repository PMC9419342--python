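id	hgvs_c	hgvs_p	mutation_type	curation
A338V	c.1013C>T	p.Ala338Val	missense	LP
A338G	c.1013C>G	p.Ala338Gly	missense	P
A150P	c.448G>C	p.Ala150Pro	missense	P
A175D	c.524C>A	p.Ala175Asp	missense	LP
N335K	c.1005C>G	p.Asn335Lys	missense	P
R304Q	c.911G>A	p.Arg304Gln	missense	P
R304W	c.910C>T	p.Arg304Trp	missense	LP
W147R	c.439T>C	p.Trp147Arg	missense	P
C134R	c.400T>C	p.Cys134Arg	missense	P
L256P	c.767T>C	p.Leu256Pro	missense	LP
Y203C	c.608A>G	p.Tyr203Cys	missense	P
G346S	c.1036G>A	p.Gly346Ser	missense	P
P184L	c.551C>T	p.Pro184Leu	missense	LP
M148T	c.443T>C	p.Met148Thr	missense	P
D156G	c.467A>G	p.Asp156Gly	missense	P
V222F	c.664G>T	p.Val222Phe	missense	LP
H254Y	c.760C>T	p.His254Tyr	missense	P
T177I	c.530C>T	p.Thr177Ile	missense	P
S61L	c.182C>T	p.Ser61Leu	missense	LP
G195R	c.583G>A	p.Gly195Arg	missense	P
K229E	c.685A>G	p.Lys229Glu	missense	P
N120Kfs*32	c.360_363delCAAA	p.Asn120LysfsTer32	frameshift	LP
E225Rfs*5	c.673_674delinsA	p.Glu225ArgfsTer5	frameshift	P
L289Ffs*10	c.865delC	p.Leu289PhefsTer10	frameshift	P
K13Nfs*7	c.39delG	p.Lys13AsnfsTer7	frameshift	LP
G57Vfs*3	c.169delG	p.Gly57ValfsTer3	frameshift	P
I74Sfs*12	c.220delA	p.Ile74SerfsTer12	frameshift	P
F102Lfs*5	c.305delT	p.Phe102LeufsTer5	frameshift	LP
S131Rfs*9	c.392delC	p.Ser131ArgfsTer9	frameshift	P
Q164Hfs*2	c.491delA	p.Gln164HisfsTer2	frameshift	P
V193Cfs*6	c.577delG	p.Val193CysfsTer6	frameshift	LP
T210Nfs*15	c.628delA	p.Thr210AsnfsTer15	frameshift	P
D245Efs*4	c.734delA	p.Asp245GlufsTer4	frameshift	P
L270Wfs*8	c.808delC	p.Leu270TrpfsTer8	frameshift	LP
E300Gfs*11	c.898delG	p.Glu300GlyfsTer11	frameshift	P
A317Rfs*3	c.948delC	p.Ala317ArgfsTer3	frameshift	P
N326Mfs*9	c.976delA	p.Asn326MetfsTer9	frameshift	LP
K341Sfs*2	c.1021delA	p.Lys341SerfsTer2	frameshift	P
P353Lfs*17	c.1057delC	p.Pro353LeufsTer17	frameshift	P
c.325-1G>C	c.325-1G>C		splicing	LP
c.325-1G>A	c.325-1G>A		splicing	P
c.112+1delG	c.112+1delG		splicing	P
c.324+1G>A	c.324+1G>A		splicing	LP
c.380-1G>A	c.380-1G>A		splicing	P
c.113-2A>G	c.113-2A>G		splicing	P
c.180+1G>T	c.180+1G>T		splicing	LP
c.181-2A>C	c.181-2A>C		splicing	P
c.443+1G>A	c.443+1G>A		splicing	P
c.444-1G>C	c.444-1G>C		splicing	LP
c.618+2T>C	c.618+2T>C		splicing	P
c.619-2A>G	c.619-2A>G		splicing	P
c.768+1G>A	c.768+1G>A		splicing	LP
c.769-1G>T	c.769-1G>T		splicing	P
c.940+1G>C	c.940+1G>C		splicing	P
c.941-2A>T	c.941-2A>T		splicing	LP
c.1046+1G>A	c.1046+1G>A		splicing	P
W296*	c.888G>A	p.Trp296Ter	nonsense	P
Q111*	c.331C>T	p.Gln111Ter	nonsense	LP
R60*	c.178C>T	p.Arg60Ter	nonsense	P
Q27*	c.79C>T	p.Gln27Ter	nonsense	P
E84*	c.250G>T	p.Glu84Ter	nonsense	LP
Y140*	c.420C>A	p.Tyr140Ter	nonsense	P
S168*	c.503C>A	p.Ser168Ter	nonsense	P
Q198*	c.592C>T	p.Gln198Ter	nonsense	LP
W235*	c.705G>A	p.Trp235Ter	nonsense	P
R267*	c.799C>T	p.Arg267Ter	nonsense	P
K311*	c.931A>T	p.Lys311Ter	nonsense	LP
E352*	c.1054G>T	p.Glu352Ter	nonsense	P
V67del	c.199_201delGTC	p.Val67del	inframe_indel	P
K108del	c.322_324delAAG	p.Lys108del	inframe_indel	LP
N160_A161del	c.478_483delAATGCC	p.Asn160_Ala161del	inframe_indel	P
L242del	c.724_726delCTG	p.Leu242del	inframe_indel	P
A284_G285insV	c.852_853insGTC	p.Ala284_Gly285insVal	inframe_indel	LP
c.545_549delinsTT	c.545_549delinsTT		indel	P
c.871_875delinsGA	c.871_875delinsGA		indel	P
EX2_4DEL	c.(112+1_113-1)_(443+1_444-1)del		cnv	LP
EX6_7DUP	c.(618+1_619-1)_(768+1_769-1)dup		cnv	P
*365Lext*5	c.1094A>T	p.Ter365LeuextTer5	stop_lost	P
M1V	c.1A>G	p.Met1Val	start_lost	LP
G210G	c.630C>T	p.Gly210=	synonymous	P
c.*33A>G	c.*33A>G		utr3	P
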