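#!/usr/bin/env python
"""Run the full intrinsic evaluation on a locally supplied corpus.

Point this at a directory of full-text articles (plain-text dialect or
JATS-like XML) and a gold-standard JSON to reproduce a full comparison
grid — macro mean ± sd of P/R/F1 and R1/R2/RSU4 per system — on real
data, e.g. the deposited benchmark annotations once converted to the
package's gold JSON schema.

Usage:
    python scripts/evaluate_benchmark.py --articles-dir corpus/ \
        --gold corpus/gold.json [--n auto] [--seed 1]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from figsummary import (
    default_n,
    evaluate_summaries,
    parse_plaintext_article,
    parse_xml_article,
    read_gold_standard,
    summarize,
)
from figsummary.summarize import SYSTEM_NAMES


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--articles-dir", type=Path, required=True)
    parser.add_argument("--gold", type=Path, required=True)
    parser.add_argument("--n", default="auto")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--systems", default=",".join(SYSTEM_NAMES),
        help="comma-separated subset of systems",
    )
    args = parser.parse_args()

    articles = {}
    for path in sorted(args.articles_dir.iterdir()):
        if path.suffix == ".xml":
            art = parse_xml_article(path.read_text(encoding="utf-8"), article_id=path.stem)
        elif path.suffix == ".txt":
            art = parse_plaintext_article(path.read_text(encoding="utf-8"), article_id=path.stem)
        else:
            continue
        articles[art.article_id] = art

    gold = read_gold_standard(str(args.gold))
    gold.validate_against(articles)
    n = default_n(gold) if args.n == "auto" else int(args.n)
    print(f"articles: {len(articles)}, figures: {len(gold.entries)}, n = {n}")

    systems = [s.strip() for s in args.systems.split(",") if s.strip()]
    summaries = []
    for (article_id, fignum) in sorted(gold.entries):
        article = articles[article_id]
        figure = article.figure(fignum)
        for name in systems:
            summaries.append(summarize(name, article, figure, n=n, seed=args.seed))

    report = evaluate_summaries(summaries, gold, articles)
    header = f"{'system':18s} {'P':>11s} {'R':>11s} {'F1':>11s} {'R1':>11s} {'R2':>11s} {'RSU4':>11s}"
    print(header)
    for system in report.systems:
        agg = report.aggregate_prf(system, "macro")
        cells = [f"{agg.precision:.2f}±{agg.precision_sd:.2f}",
                 f"{agg.recall:.2f}±{agg.recall_sd:.2f}",
                 f"{agg.f1:.2f}±{agg.f1_sd:.2f}"]
        for metric in ("R1", "R2", "RSU4"):
            mean, sd = report.aggregate_rouge(system, metric)
            cells.append(f"{mean:.2f}±{sd:.2f}")
        print(f"{system:18s} " + " ".join(f"{c:>11s}" for c in cells))


if __name__ == "__main__":
    main()
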