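# Bundled text-processing diagnosis rules (7 speech rules, 4 testing-session rules).
if journal_text is empty then more likely mild cognitive impairment
if journal_text has a large vocabulary, long sentences, and/or high sentence complexity then more likely healthy
if journal_text has a small vocabulary, short sentences, and/or low sentence complexity then more likely mild cognitive impairment
if journal_text uses positive emotion words then more likely healthy
if journal_text uses negative emotion words then more likely mild cognitive impairment
if journal_text appears to have more than 1 entry then more likely healthy
if journal_text appears to only have 1 entry then more likely mild cognitive impairment
if some interview_assessment ratings are <= 3 then more likely mild cognitive impairment
if most interview_assessment ratings are >= 4 then more likely healthy
if the interview_assessment explanations suggest the participant confidently answered the questions correctly then more likely healthy
if the interview_assessment explanations suggest the participant struggled to answer the questions correctly then more likely mild cognitive impairment
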