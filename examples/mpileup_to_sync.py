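"""Convert an mpileup snippet to the sync allele-count format.

Builds a tiny two-sample samtools mpileup file, applies a base-quality
threshold while parsing, and writes the post-filter stream as sync
(per-sample counts in A:T:C:G:N:DEL order).  The same conversion is exposed
on the command line as `pooldiv sync --format mpileup`.
"""

import io
import tempfile
from pathlib import Path

from pooldiv import read_mpileup, write_sync

PILEUP = """\
chr1\t101\tA\t6\t....,,\tIIIIII\t4\t..TT\tIIII
chr1\t102\tG\t6\t..,,C.\tIIII!I\t4\t.,.,\tIIII
chr1\t103\tT\t5\t..*,,\tIIIII\t4\t.+2AG.,,\tIIII
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "sample.pileup"
    path.write_text(PILEUP)
    # a min-base-quality of 20 drops the low-quality 'C' call at 102 ('!' = 0)
    variants = read_mpileup(path, min_base_quality=20)
    buf = io.StringIO()
    write_sync(variants, buf)
    print(buf.getvalue().rstrip())
    print("\ncolumns: chrom, pos, ref, then per sample A:T:C:G:N:DEL;")
    print("the deletion placeholder '*' at 103 is tallied as DEL, the indel")
    print("'+2AG' is consumed without affecting counts.")
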