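"""Create the checked-in fixture manifest for the end-to-end pipeline test.

Runs synth -> extract -> rank -> evaluate through the CLI on the fixed
fixture seed, cross-checks the ranking output against an independent
pandas groupby oracle computed from the mentions table, then freezes the
small outputs and sha256 hashes into tests/fixtures/.
"""

import hashlib
import json
import math
import shutil
import sys
import tempfile
from pathlib import Path

import pandas as pd
from click.testing import CliRunner

from phenotext.cli import main
from phenotext.synth import FIXTURE_SEED

REPO = Path(__file__).resolve().parents[1]
FIXDIR = REPO / "tests" / "fixtures"


def sha256(p: Path) -> str:
    return hashlib.sha256(p.read_bytes()).hexdigest()


def oracle_rankings(mentions_tsv: Path, cohort_txt: Path, k=50):
    """Independent route: pandas groupby over the mentions table."""
    m = pd.read_csv(mentions_tsv, sep="\t")
    cohort = set(cohort_txt.read_text().split())
    q = m[(m.negated == 0) & (m.experiencer == "patient")]
    # warehouse stats
    p_tot = q.patient_id.nunique()
    p_c = q.groupby("concept_id").patient_id.nunique()
    qc = q[q.patient_id.isin(cohort)]
    n_tot = len(qc)
    n_c = qc.groupby("concept_id").size()
    n_pat = qc.groupby("concept_id").patient_id.nunique()
    freq = n_pat / len(cohort)
    tfidf = (n_c / n_tot) * (p_tot / p_c.loc[n_c.index]).apply(math.log10)
    by_f = sorted(freq.index, key=lambda c: (-freq[c], c))[:k]
    by_t = sorted(tfidf.index, key=lambda c: (-tfidf[c], c))[:k]
    return by_f, by_t, freq, tfidf


def run():
    runner = CliRunner()
    tmp = Path(tempfile.mkdtemp())
    d = tmp / "bundle"
    steps = [
        ["synth", "--out", str(d), "--seed", str(FIXTURE_SEED)],
        ["extract", "--lexicon", str(d / "lexicon.tsv"), "--triggers", str(d / "triggers.tsv"),
         "--documents", str(d / "documents.jsonl"), "--out", str(tmp / "mentions.tsv"),
         "--context-table", str(tmp / "context_table.json")],
        ["rank", "--mentions", str(tmp / "mentions.tsv"), "--cohort", str(d / "cohort.txt"),
         "--lexicon", str(d / "lexicon.tsv"), "--out", str(tmp / "rankings.tsv")],
        ["evaluate", "--rankings", str(tmp / "rankings.tsv"),
         "--judgments", str(d / "judgments.tsv"), "--reference", str(d / "reference.tsv"),
         "--hierarchy", str(d / "hierarchy.tsv"), "--out", str(tmp / "report.tsv")],
    ]
    for args in steps:
        res = runner.invoke(main, args, catch_exceptions=False)
        assert res.exit_code == 0, (args, res.output)

    # cross-check pipeline ranking against the independent oracle
    from phenotext.cohort_metrics import read_rankings
    got = read_rankings(tmp / "rankings.tsv")
    by_f, by_t, freq, tfidf = oracle_rankings(tmp / "mentions.tsv", d / "cohort.txt")
    assert [rc.concept_id for rc in got["freq"]] == by_f, "frequency ranking mismatch"
    assert [rc.concept_id for rc in got["tfidf"]] == by_t, "tfidf ranking mismatch"
    for rc in got["freq"]:
        assert abs(rc.frequency - freq[rc.concept_id]) < 5e-7  # TSV carries 6 dp
        assert abs(rc.tfidf - tfidf[rc.concept_id]) < 5e-7
    print("oracle cross-check passed:", len(by_f), "concepts ranked")

    FIXDIR.mkdir(parents=True, exist_ok=True)
    for name in ("rankings.tsv", "context_table.json", "report.tsv"):
        shutil.copy(tmp / name, FIXDIR / f"expected_{name}")
    manifest = {
        "seed": FIXTURE_SEED,
        "sha256": {
            **{f"bundle/{p.name}": sha256(p) for p in sorted(d.iterdir())},
            **{n: sha256(tmp / n) for n in ("mentions.tsv", "context_table.json",
                                            "rankings.tsv", "report.tsv")},
        },
    }
    (FIXDIR / "fixture_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    print("wrote", FIXDIR / "fixture_manifest.json")
    for name in ("rankings.tsv", "context_table.json", "report.tsv"):
        print(f"expected_{name}: {(FIXDIR / ('expected_' + name)).stat().st_size} bytes")
    shutil.rmtree(tmp)


if __name__ == "__main__":
    sys.exit(run())
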