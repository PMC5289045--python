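# Deposited genome records

Place GenBank flat files (or FASTA) for the deposited plastomes here to
enable the accession-based acceptance targets and tests:

    KX198560.gb   (TK)
    KX198561.gb   (TO)
    KX198559.gb   (TB)

e.g. from NCBI efetch:

    https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=KX198560&rettype=gbwithparts&retmode=text

GenBank format is preferred over FASTA: gene-copy counts and the coding
region identity ranking need the feature annotations. This directory ships
empty because the records are not redistributable.
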