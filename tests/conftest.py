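"""Shared fixtures: tiny text fixtures generated in-memory, deterministic RNGs."""

import numpy as np
import pytest

RM_OUT = """\
   SW   perc perc perc  query      position in query           matching       repeat              position in repeat
score   div. del. ins.  sequence   begin   end        (left)   repeat         class/family      begin  end    (left)  ID

  463   1.3  0.6  1.7   chr1          101     200     (9800) +  L1-sub1       LINE/L1               1    100      (0)   1
  239  12.5  0.0  0.0   chr1          301     400     (9600) C  tRNA-sub7     SINE/tRNA             1    100      (0)   2
"""

GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t1\t1000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t1\t300\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
chr1\ttest\texon\t601\t1000\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
chr1\ttest\tCDS\t101\t300\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1
chr1\ttest\tCDS\t601\t900\t.\t+\t0\tID=geneA.c2;Parent=geneA.t1
chr1\ttest\tgene\t5001\t6000\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t5001\t5400\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttest\texon\t5001\t5400\t.\t-\t.\tID=geneB.t1e;Parent=geneB.t1
chr1\ttest\tmRNA\t5001\t6000\t.\t-\t.\tID=geneB.t2;Parent=geneB
chr1\ttest\texon\t5001\t6000\t.\t-\t.\tID=geneB.t2e;Parent=geneB.t2
chr2\ttest\tgene\t101\t900\t.\t+\t.\tID=geneC
chr2\ttest\tmRNA\t101\t900\t.\t+\t.\tID=geneC.t1;Parent=geneC
chr2\ttest\texon\t101\t900\t.\t+\t.\tID=geneC.e1;Parent=geneC.t1
"""


@pytest.fixture
def rm_out_file(tmp_path):
    p = tmp_path / "fixture.out"
    p.write_text(RM_OUT)
    return p


@pytest.fixture
def gff3_file(tmp_path):
    p = tmp_path / "fixture.gff3"
    p.write_text(GFF3)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def make_te(copy_id, chrom, start, end, te_class="LINE", family="L1", div=None):
    from retroscape.io_formats import TECopy

    return TECopy(
        copy_id=copy_id,
        chrom=chrom,
        start=start,
        end=end,
        te_class=te_class,
        family=family,
        divergence_pct=div,
    )
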