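"""ARG burden and crAssphage profiling from alignment records.

Constructs a small set of read-to-reference alignments by hand and applies
the two rule-based screens: ARG-carrying reads (alignment >=500 bp with
<50 Ns; burden per 10,000 sample reads) and crAssphage abundance/strain
assignment (70/70 primary alignment; strains need mapping quality >=5).
"""

from longmeta.alignments import AlignmentRecord
from longmeta.targeted import count_arg_reads, crassphage_profile


def aln(read, target, block, qlen=1000, cover=0.9, identity=0.92, mapq=60,
        n_count=0):
    return AlignmentRecord(
        query_id=read, query_length=qlen, query_start=0,
        query_end=int(qlen * cover), target_id=target,
        matches=int(identity * block), block_length=block, mapq=mapq,
        query_n_count=n_count,
    )


arg_alignments = [
    aln("r1", "tetW", 800),
    aln("r2", "blaTEM", 650),
    aln("r2", "tetW", 510),          # one read, two ARGs
    aln("r3", "vanA", 499),          # too short: not counted
    aln("r4", "ermB", 700, n_count=50),  # too many Ns: not counted
]
arg = count_arg_reads(arg_alignments, total_reads=1000)
print("per-ARG read counts:", arg.per_arg)
print(
    f"{arg.carrying_reads} ARG-carrying reads in {arg.total_reads} -> "
    f"{arg.rate_per_10k:.1f} per 10,000 reads"
)

crass_alignments = [
    aln(f"c{i}", "crass_strain_1", 900, mapq=60) for i in range(6)
] + [
    aln(f"c{i}", "crass_strain_2", 900, mapq=3) for i in range(6, 10)
]
profile = crassphage_profile(crass_alignments, total_reads=100)
print(
    f"\ncrAssphage abundance: {profile.abundance:.2f} "
    f"({profile.crass_reads} of {profile.total_reads} reads)"
)
print("strain counts (MQ>=5 only):", profile.per_strain)
print(
    f"assignable fraction: {profile.assignable_fraction:.2f} "
    "(low-MQ reads map ambiguously between strains)"
)
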