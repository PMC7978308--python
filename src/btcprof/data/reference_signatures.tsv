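channel	SBS1	SBS2	SBS5	SBS22	SBS40
A[C>A]A	0.00089102	0.00089502	0.003125	0.00066399	0.01091699
A[C>A]C	0.00089102	0.00089502	0.003125	0.00066399	0.00938399
A[C>A]G	0.00089102	0.00089502	0.003125	0.00066399	0.01012599
A[C>A]T	0.00089102	0.00089502	0.003125	0.00066399	0.01081599
C[C>A]A	0.00089102	0.00089502	0.003125	0.00066399	0.00907499
C[C>A]C	0.00089102	0.00089502	0.003125	0.00066399	0.01147199
C[C>A]G	0.00089102	0.00089502	0.003125	0.00066399	0.01099099
C[C>A]T	0.00089102	0.00089502	0.003125	0.00066399	0.01078799
G[C>A]A	0.00089102	0.00089502	0.003125	0.00066399	0.00950799
G[C>A]C	0.00089102	0.00089502	0.003125	0.00066399	0.00933099
G[C>A]G	0.00089102	0.00089502	0.003125	0.00066399	0.00935299
G[C>A]T	0.00089102	0.00089502	0.003125	0.00066399	0.01147899
T[C>A]A	0.00089102	0.00089502	0.003125	0.00066399	0.01027899
T[C>A]C	0.00089102	0.00089502	0.003125	0.00066399	0.00895299
T[C>A]G	0.00089102	0.00089502	0.003125	0.00066399	0.01063799
T[C>A]T	0.00089102	0.00089502	0.003125	0.00066399	0.01181499
A[C>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01104099
A[C>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.00900799
A[C>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.00974199
A[C>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00937699
C[C>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.00911499
C[C>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.01051099
C[C>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.01154499
C[C>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.01033299
G[C>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01082699
G[C>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.00974699
G[C>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.00947799
G[C>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00948899
T[C>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.00944499
T[C>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.01130499
T[C>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.01181999
T[C>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.01028499
A[C>T]A	0.01426034	0.00089502	0.003125	0.00066399	0.00992599
A[C>T]C	0.01426034	0.00089502	0.003125	0.00066399	0.01076899
A[C>T]G	0.18939855	0.00089502	0.003125	0.00066399	0.01083199
A[C>T]T	0.01426034	0.00089502	0.003125	0.00066399	0.01156399
C[C>T]A	0.01426034	0.00089502	0.003125	0.00066399	0.01178199
C[C>T]C	0.01426034	0.00089502	0.003125	0.00066399	0.00911399
C[C>T]G	0.18939855	0.00089502	0.003125	0.00066399	0.01178399
C[C>T]T	0.01426034	0.00089502	0.003125	0.00066399	0.01115499
G[C>T]A	0.01426034	0.00089502	0.003125	0.00066399	0.01149899
G[C>T]C	0.01426034	0.00089502	0.003125	0.00066399	0.01191799
G[C>T]G	0.18939855	0.00089502	0.003125	0.00066399	0.01043199
G[C>T]T	0.01426034	0.00089502	0.003125	0.00066399	0.01018499
T[C>T]A	0.01426034	0.35811024	0.003125	0.00066399	0.01078899
T[C>T]C	0.01426034	0.13429109	0.003125	0.00066399	0.00894499
T[C>T]G	0.18939855	0.08952806	0.003125	0.00066399	0.01014799
T[C>T]T	0.01426034	0.33572872	0.003125	0.00066399	0.00959899
A[T>A]A	0.00089102	0.00089502	0.003125	0.03097244	0.01041399
A[T>A]C	0.00089102	0.00089502	0.003125	0.03097244	0.00887799
A[T>A]G	0.00089102	0.00089502	0.003125	0.03097244	0.01194199
A[T>A]T	0.00089102	0.00089502	0.003125	0.03097244	0.01012199
C[T>A]A	0.00089102	0.00089502	0.003125	0.11061701	0.01158899
C[T>A]C	0.00089102	0.00089502	0.003125	0.07743261	0.01069699
C[T>A]G	0.00089102	0.00089502	0.003125	0.28760582	0.01039199
C[T>A]T	0.00089102	0.00089502	0.003125	0.09955621	0.01180499
G[T>A]A	0.00089102	0.00089502	0.003125	0.03097244	0.00919099
G[T>A]C	0.00089102	0.00089502	0.003125	0.03097244	0.01162199
G[T>A]G	0.00089102	0.00089502	0.003125	0.03097244	0.01190399
G[T>A]T	0.00089102	0.00089502	0.003125	0.03097244	0.00930799
T[T>A]A	0.00089102	0.00089502	0.003125	0.03097244	0.01073599
T[T>A]C	0.00089102	0.00089502	0.003125	0.03097244	0.00983599
T[T>A]G	0.00089102	0.00089502	0.003125	0.03097244	0.00933599
T[T>A]T	0.00089102	0.00089502	0.003125	0.03097244	0.00898399
A[T>C]A	0.00089102	0.00089502	0.046875	0.00066399	0.01083799
A[T>C]C	0.00089102	0.00089502	0.046875	0.00066399	0.01010499
A[T>C]G	0.00089102	0.00089502	0.046875	0.00066399	0.01090499
A[T>C]T	0.00089102	0.00089502	0.046875	0.00066399	0.01006099
C[T>C]A	0.00089102	0.00089502	0.046875	0.00066399	0.01173399
C[T>C]C	0.00089102	0.00089502	0.046875	0.00066399	0.01055599
C[T>C]G	0.00089102	0.00089502	0.046875	0.00066399	0.00950699
C[T>C]T	0.00089102	0.00089502	0.046875	0.00066399	0.00899499
G[T>C]A	0.00089102	0.00089502	0.046875	0.00066399	0.01175699
G[T>C]C	0.00089102	0.00089502	0.046875	0.00066399	0.01031899
G[T>C]G	0.00089102	0.00089502	0.046875	0.00066399	0.01033799
G[T>C]T	0.00089102	0.00089502	0.046875	0.00066399	0.00986799
T[T>C]A	0.00089102	0.00089502	0.046875	0.00066399	0.01166099
T[T>C]C	0.00089102	0.00089502	0.046875	0.00066399	0.01114499
T[T>C]G	0.00089102	0.00089502	0.046875	0.00066399	0.00930499
T[T>C]T	0.00089102	0.00089502	0.046875	0.00066399	0.01073699
A[T>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01171699
A[T>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.01018699
A[T>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.00964499
A[T>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00900499
C[T>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01035899
C[T>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.00962199
C[T>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.01000399
C[T>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00979299
G[T>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01052199
G[T>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.01172399
G[T>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.01180599
G[T>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00927099
T[T>G]A	0.00089102	0.00089502	0.003125	0.00066399	0.01132599
T[T>G]C	0.00089102	0.00089502	0.003125	0.00066399	0.01062199
T[T>G]G	0.00089102	0.00089502	0.003125	0.00066399	0.01146799
T[T>G]T	0.00089102	0.00089502	0.003125	0.00066399	0.00990899
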