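# Default negative-word lexicon: short hand-curated list of unambiguously
# negative English words observed in COVID-era tweet streams.
# The printed source list contains two duplicated entries ("shame", "failed");
# they are preserved here verbatim so the raw token count is reproducible,
# and collapsed on load.
panic, fear, sad, mental, mind, sorry, shame, hate, hell, violence,
bad, feel, feeling, shit, worst, worse, blame, lonely, horrible,
chaos, mad, ruined, anxiety, stress, stressed, phobia, abuse,
shame, hurt, disorder, loneliness, turmoil, anger, horror,
rage, fate, nervous, restless, depression, grief, worry, stupid
worried, angst, depressed, suicide, suffer, suffering,
uncertainty, uneasy, sadness, afraid, alone, suicidal, mood,
tension, anxious, desperate, dismal, exhausted, insecure,
distress, distressed, frustration, disgusting, boredom, bored,
insane, stupidity, bullshit, uncertain, displeased, upset, outrage,
uncomfortable, melancholy, overwhelmed, pessimistic, unhappy,
ass, damn, covidiot, terrify, terrified, terrifying, distrust,
scare, scared, scaring, dread, failed, failed, failure, crisis,
fuck, fucking, miserable, regret, shock, shocked, rape, mess,
negligence, betrayed, cry, crying, idiot, idiots, selfish, upheaval
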