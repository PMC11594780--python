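# Editable pattern rule table for CZE-IS index interpretation.
#
# Patterns are tried in `precedence` order; the first whose conditions hold
# is the call, otherwise `fallback` applies.  Condition keys:
#   any:            at least one listed (index, flags) trigger fires in some zone
#   require_normal: the listed indexes must be flagged normal in every zone
#   forbid:         none of the listed (index, flags) may occur in any zone
# Flags are low | normal | high | undefined.
precedence:
  - suspect_monoclonal
  - polyclonal
  - hypogammaglobulinemia
  - normal
fallback: mixed_other
patterns:
  suspect_monoclonal:
    any:
      - index: sharpness
        flags: [high]
      - index: light_chain
        flags: [high, low, undefined]
  polyclonal:
    # A low sharpness index (an unusually blunt peak) argues against
    # monoclonality and does not block the polyclonal call; only a high or
    # undefined sharpness, or an abnormal light-chain balance, does.
    any:
      - index: igg
        flags: [high]
      - index: iga
        flags: [high]
      - index: igm
        flags: [high]
    forbid:
      - index: sharpness
        flags: [high, undefined]
      - index: light_chain
        flags: [low, high, undefined]
  hypogammaglobulinemia:
    any:
      - index: igg
        flags: [low]
      - index: iga
        flags: [low]
      - index: igm
        flags: [low]
    require_normal: [sharpness, light_chain]
    forbid:
      - index: igg
        flags: [high]
      - index: iga
        flags: [high]
      - index: igm
        flags: [high]
  normal:
    require_normal: [sharpness, light_chain, igg, iga, igm]
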