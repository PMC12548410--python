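"""Fetch the published proviral sequence sets from NCBI GenBank.

Downloads the full-length / env proviral records for each virus group into
``data/genbank/proviruses.fa`` with a ``data/genbank/manifest.tsv`` mapping
ids to virus and variant class.  Needs network access to NCBI E-utilities;
run once, then the table-reproduction acceptance tests consume the cache.

Two published groups are NOT fetchable from GenBank by accession and are
skipped here: the endogenous MuLV set (Mpmv/Pmv/Xmv names from a journal
supplement) and the phaCin-beta set (pCi names from a journal supplement).
Place those alignments manually as ``data/enmulv_alignment.fa`` if you have
them; the hypermutation-prevalence test consumes that file.

Usage:  python scripts/fetch_genbank.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

from Bio import Entrez, SeqIO

# virus -> variant class -> accession list, kept verbatim from the published
# sequence table (duplicate accessions in the source list are kept as
# replicate entries so group sizes match the published N)
ACCESSIONS: dict[str, dict[str, list[str]]] = {
    "FeLV": {
        "exogenous": ["AB672612.1", "AB672612.1", "M18247.1", "MZ964580.1",
                      "AF052723.1", "AF052723.1", "MT129531.1", "NC_001940.1"],
        "endogenous": ["AY364318.1", "LC196053.1", "LC196055.1", "OP595707.1",
                       "AY364319.1", "LC196054.1", "OP595706.1", "OP595708.1"],
    },
    "MuLV": {
        "exogenous": ["KY574504.1", "KY574507.1", "KY574510.1", "KY574513.1",
                      "KY574516.1", "MG525170.1", "KY574505.1", "KY574508.1",
                      "KY574511.1", "KY574514.1", "KY574517.1", "KY574506.1",
                      "KY574509.1", "KY574512.1", "KY574515.1", "KY574518.1"],
    },
    "KoRV": {
        # env sequences: endogenous = KoRV-A, exogenous = subtypes B-F
        "endogenous": ["AB721500.1", "JQ244835.1", "JQ244838.1", "KF786281.1",
                       "KF786284.1", "NC_039228.1", "AB823238.1", "JQ244836.1",
                       "JQ244839.1", "KF786282.1", "KF786285.1", "AF151794.2",
                       "JQ244837.1", "KF786280.1", "KF786283.1", "KF786286.1"],
        "exogenous": ["AB822553.1", "AB828005.1", "KP792564.1", "KU533852.1",
                      "AB828004.1", "KC779547.1", "KP792565.1", "KU533853.1"],
    },
    "MMTV": {
        "endogenous": ["AC122322.4", "AF228550.1", "NG_005612.1", "AC140344.3",
                       "AL683884.26"],
        "exogenous": ["AF033807.1", "AF228552.1", "M15122.1", "AF228551.1",
                      "D16249.1", "NC_001503.1"],
    },
    "JSRV": {
        "endogenous": ["AF136224.1", "EF680297.1", "EF680302.1", "EF680307.1",
                       "EF680314.1", "MF175071.1", "AF136225.1", "EF680298.1",
                       "EF680303.1", "EF680308.1", "MF175067.1", "AF153615.1",
                       "EF680299.1", "EF680304.1", "EF680309.1", "MF175068.1",
                       "DQ838493.1", "EF680300.1", "EF680305.1", "EF680310.1",
                       "MF175069.1", "EF680296.1", "EF680301.1", "EF680306.1",
                       "EF680312.1", "MF175070.1"],
        "exogenous": ["AF105220.1", "CQ964469.1", "KP691837.1", "NC_001494.1",
                      "AF357971.1", "DQ838494.1", "M80216.1",
                      "FJ744146.1", "FJ744149.1", "GU292315.1", "GU292318.1",
                      "PP707036.1", "FJ744147.1", "FJ744150.1", "GU292316.1",
                      "KC189895.1", "FJ744148.1", "GU292314.1", "GU292317.1",
                      "NC_007015.1"],
    },
    "PERV-A": {
        "endogenous": ["AF435966.1", "AY099323.1", "HM159246.1", "KY484771.1",
                       "AJ133817.1", "EF133960.1", "HQ540591.1", "OR574834.1"],
    },
    "PERV-B": {
        "endogenous": ["AJ133816.1", "AJ293657.1", "EU523109.1", "HQ536010.1",
                       "HQ540594.1", "AJ133818.1", "AY056035.1", "HQ536008.1",
                       "HQ536011.1", "HQ540595.1", "AJ279057.1", "AY099324.1",
                       "HQ536009.1", "HQ540593.1"],
    },
    "PERV-C": {
        "endogenous": ["AF038599.1", "AY570980.1", "HQ536014.1", "KC116219.1",
                       "KY352351.2", "AF038600.1", "HQ536012.1", "HQ536015.1",
                       "KC116220.1", "MT984604.1", "AM229312.2", "HQ536013.1",
                       "HQ536016.1", "KC116221.1"],
    },
}


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default="anonymous@example.org")
    ap.add_argument("--out-dir", default="data/genbank")
    args = ap.parse_args()

    Entrez.email = args.email
    out_dir = Path(args.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    unique = sorted({a for v in ACCESSIONS.values() for lst in v.values() for a in lst})
    print(f"fetching {len(unique)} unique records ...")
    by_acc = {}
    for i in range(0, len(unique), 20):
        batch = unique[i : i + 20]
        handle = Entrez.efetch(db="nuccore", id=",".join(batch),
                               rettype="fasta", retmode="text")
        for rec in SeqIO.parse(handle, "fasta"):
            key = rec.id
            by_acc[key] = str(rec.seq).upper()
        handle.close()
        time.sleep(0.4)

    missing = [a for a in unique if a not in by_acc]
    if missing:
        print(f"WARNING: {len(missing)} records not retrieved: {missing}",
              file=sys.stderr)

    fa = out_dir / "proviruses.fa"
    manifest = out_dir / "manifest.tsv"
    with open(fa, "w") as fh, open(manifest, "w") as mh:
        for virus, classes in ACCESSIONS.items():
            for klass, accs in classes.items():
                for j, acc in enumerate(accs):
                    if acc not in by_acc:
                        continue
                    rid = f"{acc}__{j}" if accs.count(acc) > 1 else acc
                    fh.write(f">{rid} virus={virus} class={klass}\n")
                    seq = by_acc[acc]
                    for k in range(0, len(seq), 70):
                        fh.write(seq[k : k + 70] + "\n")
                    mh.write(f"{rid}\t{virus}\t{klass}\n")
    print(f"wrote {fa} and {manifest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
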