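"""From a VCF with panel + archaic genotypes to the HMM's site table.

Builds a small VCF on the fly (two panel individuals, one archaic, ancestral
alleles in the AA INFO tag), extracts the informative sites, attaches genetic
positions from a recombination map and writes the TSV site table that the
``elscan`` CLI consumes.
"""

import tempfile
from pathlib import Path

import elscan as E

VCF = """##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tH1\tH2\tNEA
1\t1200\t.\tA\tG\t.\tPASS\tAA=A\tGT\t1|1\t1|1\t1|1
1\t3400\t.\tC\tT\t.\tPASS\tAA=C\tGT\t1|1\t1|1\t0|0
1\t5100\t.\tG\tA\t.\tPASS\tAA=G\tGT\t0|1\t0|0\t0|0
1\t7800\t.\tT\tC\t.\tPASS\tAA=T\tGT\t1|0\t1|1\t1|1
1\t9900\t.\tA\tC\t.\tPASS\tAA=C\tGT\t0|1\t0|0\t0|0
1\t12000\t.\tC\tG\t.\tPASS\tAA=T\tGT\t0|1\t0|0\t0|0
"""

with tempfile.TemporaryDirectory() as d:
    vcf_path = Path(d) / "toy.vcf"
    vcf_path.write_text(VCF)
    seq, counters = E.sites_from_vcf(vcf_path, ["H1", "H2"], ["NEA"])
    print("conversion counters:", dict(counters))
    rec_map = E.RecombinationMap.uniform(1.2, 100_000, name="toy")
    E.annotate_gpos(seq, rec_map)
    out = Path(d) / "sites.tsv"
    E.write_site_table(seq, out)
    print(out.read_text())
print("columns: 1-based position, derived count among the 4 panel "
      "chromosomes (4/4 = fixed derived), archaic allele (A ancestral / "
      "D derived), cumulative cM under the 'toy' map")
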