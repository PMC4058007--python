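# Keyword rules for assigning toxin/enzyme categories from best-hit
# descriptions. Rule order is priority: the first rule whose keyword
# occurs (case-insensitively) in the hit description wins. Hits with an
# e-value above max_evalue, or transcripts without any hit, are "no_hit";
# hits matching no rule are "other".
max_evalue: 1.0e-5
categories:
  - name: latrotoxin
    keywords: [latrotoxin, latroinsectotoxin, latrocrustotoxin]
  - name: latrodectin
    keywords: [latrodectin, "alpha-latrotoxin associated", LMWP]
  - name: ICK
    keywords: [CSTX, ctenitoxin, inhibitor cystine knot, knottin, ICK]
  - name: CRISP
    keywords: [CRISP, cysteine-rich secretory]
  - name: metalloprotease
    keywords: [metalloprotease, metalloproteinase, metallopeptidase, M13]
  - name: serine protease
    keywords: [serine protease, serine proteinase, serine-type endopeptidase]
  - name: hyaluronidase
    keywords: [hyaluronidase, hyalurononglucosaminidase]
  - name: chitinase
    keywords: [chitinase]
  - name: leucine-rich repeat
    keywords: [leucine-rich repeat, leucine rich repeat, LRR]
  - name: lipase
    keywords: [lipase, phospholipase, AB hydrolase]
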