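# File formats

All formats are plain text; writers produce deterministic output
(identical inputs → byte-identical files). Undefined statistics are
encoded as `NA`. Files ending in `.gz` are read and written
gzip-compressed where noted.

## SFS file (`*.sfs`)

One line of whitespace-separated reals, length 2n+1; entry k is the
(possibly fractional) number of sites with k derived alleles.
Read/write: `ngstheta.spectrum.read_sfs` / `write_sfs`. Probability-
scale spectra (summing to 1) use the same format.

## Beagle genotype likelihoods (`*.beagle`)

Header `marker allele1 allele2 Ind0 Ind0 Ind0 ...` (three columns per
individual), then one row per site. `marker` is `chrom_position`;
alleles are coded 0..3 = A,C,G,T; the three likelihoods of carrying
0/1/2 copies of `allele2` are normalized to sum to 1 per individual.
Read/write: `ngstheta.likelihoods.read_beagle` / `write_beagle`
(reader returns max-0 log likelihoods).

## SAF table (`*.saf.tsv[.gz]`)

Tab-separated, no header: `chrom`, `position` (1-based), then 2n+1
log-likelihood values log Pr(D|x=j), max-normalized to 0 per site.
Gzip-transparent. Read/write: `ngstheta.saf.read_saf` / `write_saf`.

## Window TSV

Header line, then one row per window:

    chrom  winStart  winEnd  winCenter  nSites  tW  tP  tFL  tH  S  TajimaD  FuLiD  FuLiF

`winStart` 1-based inclusive, `winEnd` exclusive, `winCenter` =
winStart + window//2, `nSites` = informative sites used. Read/write:
`ngstheta.scan.read_windows` / `write_windows`.

## Genotype matrix TSV

Header `chrom position Ind0 ... Ind{n-1}`, one row per segregating
site, entries are derived-allele dosages in {0,1,2}. Writer:
`ngstheta.simulate.write_genotypes`; the CLI `call` command writes the
same layout for called genotypes (all positions).

## ms/msms input

Standard ms text: replicates introduced by `//`, then `segsites: K`,
`positions: ...` (relative in [0,1)), then one 0/1 haplotype row per
chromosome. Positions are mapped to bp by floor(pos·L)+1 with
collisions shifted to the next free bp; consecutive haplotypes are
paired into diploids. Reader: `ngstheta.simulate.read_ms`.
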