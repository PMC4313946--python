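"""Dataset statistics of the published benchmark annotations.

Recomputes, from the shipped per-article figure and sentence counts, the
totals and micro/macro sentences-per-figure averages of the two public
gold standards, and the summary length n derived from each (the ceiling
of the micro average).  Displayed averages are truncated to two decimals,
the benchmark's reporting convention.
"""

from figsummary import default_n
from figsummary.benchmark import gs1_statistics, gs2_statistics
from figsummary.evaluate import format_average

for name, stats in (("GS1", gs1_statistics()), ("GS2", gs2_statistics())):
    print(f"{name}: {len(stats.per_article)} articles, "
          f"{stats.total_figures} figures, {stats.total_sentences} annotated sentences")
    print(f"  micro avg sentences/figure: {format_average(stats.micro_average)}")
    print(f"  macro avg sentences/figure: {format_average(stats.macro_average)}")
    print(f"  derived summary length n:   {default_n(stats.micro_average)}")
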