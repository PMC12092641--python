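"""Build the four aggression networks for one pen and extract centralities.

ALL holds every agonistic act (directed, duration-weighted); UNI the
unreciprocated damaging aggression; FIGHT the mutual fights (undirected);
WIN the decided fights, directed winner -> loser and weighted by count.
"""

import pignet as pn
from pignet.bouts import segment_fights
from pignet.centrality import centrality_table, redundancy_screen
from pignet.events import filter_subtle
from pignet.networks import build_network, simplify
from pignet.pipeline import analyse_networks
from pignet.synthetic import _frame_to_event_list

study = pn.generate_study(n_pens=2, seed=3)
pen_id = study.roster["pen_id"].iloc[0]
roster = study.roster[study.roster["pen_id"] == pen_id]
events = filter_subtle(
    [
        e
        for e in _frame_to_event_list(study.events)
        if e.actor in set(roster["pig_id"])
    ]
)
bouts = segment_fights(events)
print(f"{pen_id}: {len(events)} events, {len(bouts)} fight bouts, "
      f"{sum(b.decided for b in bouts)} decided")

for nt in ("ALL", "UNI", "FIGHT", "WIN"):
    net = simplify(build_network(events, bouts, nt, roster))
    print(f"  {nt:<6} {net.graph.number_of_edges():>3} edges "
          f"({'directed' if net.directed else 'undirected'})")

table = centrality_table(simplify(build_network(events, bouts, "ALL", roster)))
top = (
    table[table.metric == "w_outdegree"]
    .nlargest(3, "normalised")[["pig", "raw", "normalised"]]
)
print("\nmost aggressive pigs (weighted outdegree, seconds given per "
      "potential opponent):")
print(top.to_string(index=False))

# the redundancy screen flags weighted metrics that duplicate their
# unweighted counterparts (|r| > 0.8) and would not be analysed separately
full = analyse_networks(study.roster, study.events)
print("\nredundancy screen:")
print(redundancy_screen(full).to_string(index=False))
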