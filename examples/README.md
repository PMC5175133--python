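# Example inputs

Small synthetic fixtures for trying the CLI. All four files are generated by
`profam simulate` and can be regenerated exactly with:

```sh
profam simulate family --n 20 --min-length 80 --max-length 160 \
    --bias-residues KRH --bias-strength 0.18 --prefix pos --seed 101 \
    --out examples/positive.fasta
profam simulate family --n 20 --min-length 80 --max-length 160 \
    --prefix neg --seed 102 --out examples/negative.fasta
profam simulate alignment --clades 4 --leaves-per-clade 2 --length 300 \
    --within 0.05 --between 0.3 --seed 7 --out examples/alignment.fasta
profam simulate ct --n-per-group 8 --genes DEPDC1B --effect -2.5 \
    --noise-sd 0.5 --seed 11 --out examples/ct.csv
```

- `positive.fasta` / `negative.fasta` — two synthetic protein families; the
  positive one is compositionally biased toward K/R/H.
- `alignment.fasta` — gap-free aligned FASTA with four well-separated clades
  of two leaves each, for `profam njtree`.
- `ct.csv` — a synthetic qPCR Ct table with a 2.5-cycle case shift of gene
  DEPDC1B (about 5.7-fold up-regulation), for `profam qpcr compare`.
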