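"""Published worked example: one demultiplexed 454 read from a Collembola
COI amplicon pool, its unique-sequence form, the pipeline output it
collapses into, the amplification primers, and the family-wide ambiguity
consensus built from 1,556 reference sequences.

These strings are the printed example that accompanies the original
pipeline description; they double as regression fixtures (the raw read's
header declares ``length = 354``, and removing its first 18 bases must
reproduce the unique-sequence record byte for byte).
"""

#: Forward Sanger/454 amplification primer (degenerate, 25 nt).
FORWARD_PRIMER = "TTTCAACAAATCATAARGAYATYGG"

#: Fully degenerate reverse primer (not trimmed by the pipeline; reads are
#: truncated upstream of it).
REVERSE_PRIMER = "CANCCNGTNCCNGCNCCNCTYTC"

#: Declared length of the raw demultiplexed read, from its FASTA header.
RAW_READ_DECLARED_LENGTH = 354

#: Number of 5' bases removed from the raw read to obtain the published
#: unique-sequence record (the primer's 3'-terminal 7 bases are retained).
WORKED_EXAMPLE_TRIM = 18

RAW_READ_ID = "GGQCYR401C2J7Z"

RAW_READ = (
    "TTTCAACAAATCATAAGG"
    "ATATTGGAACAATATATCTAATACTAGGATCCTGATCAGCTTTTATAGGGACTGCTTTTAGTATCCTGATC"
    "CGTATAGAACTAGGCCAACCTGGGACCCTGATTGGAAATGATCAAATCTACAATGTTATGGTGACTGCTCA"
    "TGCTTTTTGTAATAATTTTCTTTATAGTTATACCAATTATGATTGGAGGGTTTGGGAATTGATTAGTCCCC"
    "CTAATAATTGGGGCTCCTGATATAGCCTTCCCACGTATAAATAATATAAGTTTCTGATTACTCCCCCCTTC"
    "CCTTACCTTATTAGTCGCGGGAGGTTTAGTAGAAAGAGCGGCAGGAACAGGA"
)

#: The read after unique-sequence preparation (header ``>GGQCYR401C2J7Z_1``).
UNIQUE_SEQUENCE_OUTPUT = (
    "ATATTGGAACAATATATCTAATACTAGGATCCTGATCAGCTTTTATAGGGACTGCTTTTAGTATCCTGATC"
    "CGTATAGAACTAGGCCAACCTGGGACCCTGATTGGAAATGATCAAATCTACAATGTTATGGTGACTGCTCA"
    "TGCTTTTTGTAATAATTTTCTTTATAGTTATACCAATTATGATTGGAGGGTTTGGGAATTGATTAGTCCCC"
    "CTAATAATTGGGGCTCCTGATATAGCCTTCCCACGTATAAATAATATAAGTTTCTGATTACTCCCCCCTTC"
    "CCTTACCTTATTAGTCGCGGGAGGTTTAGTAGAAAGAGCGGCAGGAACAGGA"
)

#: The denoised pipeline output record the read contributes to
#: (header ``>Seq1_2343``: 2,343 reads collapsed onto this haplotype).
PIPELINE_OUTPUT_SEQUENCE = (
    "ATATTGGAACAATATATCTAATACTAGGATCCTGATCAGCTTTTATAGGGACTGCTTTTAGTATCCTGATC"
    "CGTATAGAACTAGGCCAACCTGGGACCCTGATTGGAAATGATCAAATCTACAATGTTATGGTGACTGCTCA"
    "TGCTTTTTGTAATAATTTTCTTTATAGTTATACCAATTATGATTGGAGGGTTTGGGAATTGATTAGTCCCC"
    "CTAATAATTGGGGCTCCTGATATAGCCTTCCCACGTATAAATAATATAAGTTTCTGATTACTCCCCCCTTC"
    "CCTTACCTTATTAGTCGCGGGAGGTTTAGT"
)

#: Collembola-wide IUPAC ambiguity consensus of the 658-nt COI barcode
#: (union over 1,556 reference sequences; visibly N-rich).
COLLEMBOLA_CONSENSUS = (
    "NHNNNNNTNNNTNNWNHTNKSNNNNNKNNNNNSNHYNNYNGGNDYNDNNYTNARNNYNNNNNTNNSNNNN"
    "RANNTNRSNVRNNYNRGNNNNNWNNTNRRNNRNGANCANVYNTANAAYRYNNYDRTNACNKCNCANGCNK"
    "TYDYNATRATNTTYTTYRYDGTNAKNCCNNTHWTRVTHGGNGGNHTHGGNAANTKRHTNVTNCCNNTNAT"
    "RVTNRRNKCNSCNGAYATNKCNTTNCCNCGNHTNANNAAYHTRAGNTTYTGRYTNYTNCCNCCNDSNHTN"
    "NNNNTNNTNNBNNNNRGNDSNNYNDBNNANDNNGRNDNNGGNACNGGNTGRNNNNYNTAYCCNCCNNTNK"
    "CNDVNNNNNYNDBNCANNNNGGNNBNDSNRTNGANNTNDNNATYTTYWSNYTNCANYYNRCNGGNRYNNS"
    "NTMNATYYTNGGNGCNRTNARYTTYANNWSNWCNDBHDDNNAYATNNRNNNNNNNNNNNTNNNNTGRRAN"
    "NDNNYNHBNYTNYTNNBNTGNDSNRTNHWHNTNACNDCNDYHYTNYTNBYNNYNDSNHTNCCNKTNNTNN"
    "NNGGNGCNRTNWCNATRYTNNTNWYNGAYCGNAANNTNAANNCNDSNTTYTTYNNNCCNDSNGGNGGNGN"
    "NGANYMNRWHYTNTWNCANCNYHWNNYY"
)
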