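# Breed-relevant variant definitions (UU_Cfam_GSD_1.0 coordinates).
# Non-SNV alleles (deletion/duplication/structural haplotypes) are matched by
# exact record coordinates plus a symbolic alt descriptor — no realignment.
- label: SOD1_c118GA
  trait: Degenerative myelopathy
  omia_id: 000263-9615
  gene: SOD1
  chrom: "31"
  pos: 27123057
  ref: G
  alt: A
- label: SOD1_c52AT
  trait: Degenerative myelopathy
  omia_id: 000263-9615
  gene: SOD1
  chrom: "31"
  pos: 27118886
  ref: A
  alt: T
- label: SP110_42620442
  trait: Degenerative myelopathy modifier
  omia_id: 000263-9615
  gene: SP110
  chrom: "25"
  pos: 42620442
  ref: G
  alt: A
- label: SP110_42623004
  trait: Degenerative myelopathy modifier
  omia_id: 000263-9615
  gene: SP110
  chrom: "25"
  pos: 42623004
  ref: C
  alt: T
- label: SP110_42628769
  trait: Degenerative myelopathy modifier
  omia_id: 000263-9615
  gene: SP110
  chrom: "25"
  pos: 42628769
  ref: C
  alt: T
- label: SP110_42631341
  trait: Degenerative myelopathy modifier
  omia_id: 000263-9615
  gene: SP110
  chrom: "25"
  pos: 42631341
  ref: G
  alt: A
- label: SP110_42633078
  trait: Degenerative myelopathy modifier
  omia_id: 000263-9615
  gene: SP110
  chrom: "25"
  pos: 42633078
  ref: T
  alt: A
- label: GFAP_18459694
  trait: Alexander disease
  omia_id: 001208-9615
  gene: GFAP
  chrom: "9"
  pos: 18459694
  ref: G
  alt: A
- label: IGF1_41511739
  trait: Height
  omia_id: 002524-9615
  gene: IGF1
  chrom: "15"
  pos: 41511739
  ref: T
  alt: C
- label: MSRB3_8395407del
  trait: Ear type
  omia_id: 000319-9615
  gene: MSRB3
  chrom: "10"
  pos: 8395407
  ref: TTTATTTTAT
  alt: <DEL>
- label: FGF5_35475211
  trait: Hair length
  omia_id: 000439-9615
  gene: FGF5
  chrom: "32"
  pos: 35475211
  ref: G
  alt: A
- label: FGF5_35475230dup
  trait: Hair length
  omia_id: 000439-9615
  gene: FGF5
  chrom: "32"
  pos: 35475230
  ref: N
  alt: <DUP>
- label: FGF5_35475218del
  trait: Hair length
  omia_id: 000439-9615
  gene: FGF5
  chrom: "32"
  pos: 35475218
  ref: N
  alt: <DEL>
- label: FGF5_35486609
  trait: Hair length
  omia_id: 000439-9615
  gene: FGF5
  chrom: "32"
  pos: 35486609
  ref: A
  alt: T
- label: FGF5_35494497
  trait: Hair length
  omia_id: 000439-9615
  gene: FGF5
  chrom: "32"
  pos: 35494497
  ref: C
  alt: A
- label: ASIP_black_back
  trait: Coat color
  omia_id: 000601-9615
  gene: ASIP
  chrom: "24"
  pos: 23863804
  ref: N
  alt: <BLACK_BACK_HAPLOTYPE>
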