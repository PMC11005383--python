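# Scoring configurations for the five therapy-intensity scales.
# Version: til-scale-configs-1
#
# Each scale maps (item, sub-item level) -> a non-negative integer score.
# An item absent from a scale's table is excluded from that scale (it
# contributes nothing).  Binary items use the single level "present".
#
# Aggregation rules:
#   sum_of_item_maxima : the highest applicable score per item, summed
#                        over the scale's items (TIL, uwTIL, PILOT, TIL1987)
#   max_over_subitems  : the maximum score among administered sub-items,
#                        0 when none are administered (TILBasic)
schema: til-scale-configs-1

items:
  head_position:      {kind: binary}
  sedation:           {kind: ordinal, levels: [low, higher, metabolic]}
  nmb:                {kind: binary}
  csf_drainage:       {kind: ordinal, levels: [low, high]}
  fluid_loading:      {kind: binary}
  vasopressor:        {kind: binary}
  hypocapnia:         {kind: ordinal, levels: [mild, moderate, intensive]}
  mannitol:           {kind: ordinal, levels: [low, high]}
  hypertonic_saline:  {kind: ordinal, levels: [low, high]}
  temperature:        {kind: ordinal, levels: [fever_control, cooling, hypothermia]}
  intracranial_op:    {kind: binary}
  dc:                 {kind: binary}

scales:
  TIL:
    aggregation: sum_of_item_maxima
    max_total: 38
    scores:
      head_position:     {present: 1}
      sedation:          {low: 1, higher: 2, metabolic: 5}
      nmb:               {present: 3}
      csf_drainage:      {low: 2, high: 3}
      fluid_loading:     {present: 1}
      vasopressor:       {present: 1}
      hypocapnia:        {mild: 1, moderate: 2, intensive: 4}
      mannitol:          {low: 2, high: 3}
      hypertonic_saline: {low: 2, high: 3}
      temperature:       {fever_control: 1, cooling: 2, hypothermia: 5}
      intracranial_op:   {present: 4}
      dc:                {present: 5}

  # Unweighted variant: sub-item scores replaced by the ascending rank
  # index within each item.
  uwTIL:
    aggregation: sum_of_item_maxima
    max_total: 21
    scores:
      head_position:     {present: 1}
      sedation:          {low: 1, higher: 2, metabolic: 3}
      nmb:               {present: 1}
      csf_drainage:      {low: 1, high: 2}
      fluid_loading:     {present: 1}
      vasopressor:       {present: 1}
      hypocapnia:        {mild: 1, moderate: 2, intensive: 3}
      mannitol:          {low: 1, high: 2}
      hypertonic_saline: {low: 1, high: 2}
      temperature:       {fever_control: 1, cooling: 2, hypothermia: 3}
      intracranial_op:   {present: 1}
      dc:                {present: 1}

  # Condensed five-category scale (0-4).  Neuromuscular blockade is
  # excluded; fever control is scored at the basic-care tier (1).
  TILBasic:
    aggregation: max_over_subitems
    max_total: 4
    scores:
      head_position:     {present: 1}
      sedation:          {low: 1, higher: 2, metabolic: 4}
      csf_drainage:      {low: 2, high: 3}
      fluid_loading:     {present: 2}
      vasopressor:       {present: 2}
      hypocapnia:        {mild: 2, moderate: 3, intensive: 4}
      mannitol:          {low: 2, high: 3}
      hypertonic_saline: {low: 2, high: 3}
      temperature:       {fever_control: 1, cooling: 3, hypothermia: 4}
      intracranial_op:   {present: 4}
      dc:                {present: 4}

  # Pediatric Intensity Level of Therapy scale, adapted to the TIL item
  # set with a daily assessment frequency.
  PILOT:
    aggregation: sum_of_item_maxima
    max_total: 38
    scores:
      sedation:          {low: 1, higher: 1, metabolic: 5}
      nmb:               {present: 2}
      csf_drainage:      {low: 4, high: 5}
      vasopressor:       {present: 2}
      hypocapnia:        {mild: 1, moderate: 2, intensive: 4}
      mannitol:          {low: 2, high: 3}
      hypertonic_saline: {low: 3, high: 3}
      temperature:       {fever_control: 1, cooling: 3, hypothermia: 5}
      intracranial_op:   {present: 4}
      dc:                {present: 5}

  # The original 1987 15-point scale, adapted to the TIL item set with a
  # daily assessment frequency.
  TIL1987:
    aggregation: sum_of_item_maxima
    max_total: 15
    scores:
      sedation:          {low: 1, higher: 1, metabolic: 4}
      nmb:               {present: 1}
      csf_drainage:      {low: 1, high: 2}
      hypocapnia:        {mild: 1, moderate: 1, intensive: 2}
      mannitol:          {low: 3, high: 6}
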