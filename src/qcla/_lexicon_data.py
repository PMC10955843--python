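"""Open substitute lexicon: 63 psychologically relevant word categories.

The proprietary LIWC 2015 dictionary cannot be redistributed, so the
package ships this openly authored substitute.  Category names follow the
field's standard inventory (function words, affect, social, cognitive
processes, biological processes, drives, relativity, personal concerns);
the word lists are short, hand-written seeds with trailing-asterisk
wildcards in the LIWC prefix convention.  They are adequate for testing
the scoring machinery and for synthetic cohorts; they are NOT a
reconstruction of any licensed dictionary.
"""

SUBSTITUTE_LEXICON: dict[str, list[str]] = {
    # --- function words -------------------------------------------------
    "function words": ["the", "a", "an", "and", "or", "but", "of", "to", "in", "it", "is", "am", "are", "was", "not", "very"],
    "pronouns": ["i", "me", "my", "we", "us", "our", "you", "your", "he", "she", "they", "them", "it", "this", "that"],
    "personal pronouns": ["i", "me", "my", "mine", "we", "us", "our", "you", "your", "he", "him", "she", "her", "they", "them"],
    "i": ["i", "me", "my", "mine", "myself"],
    "we": ["we", "us", "our", "ours", "ourselves"],
    "you": ["you", "your", "yours", "yourself"],
    "shehe": ["he", "him", "his", "she", "her", "hers"],
    "they": ["they", "them", "their", "theirs", "themselves"],
    "impersonal pronouns": ["it", "this", "that", "these", "those", "something", "anything", "nothing", "everything"],
    "articles": ["a", "an", "the"],
    "prepositions": ["to", "of", "in", "on", "at", "for", "with", "about", "over", "under", "between"],
    "auxiliary verbs": ["am", "is", "are", "was", "were", "be", "been", "have", "has", "had", "do", "does", "will", "would", "can", "could", "should"],
    "adverbs": ["very", "really", "quite", "fairly", "often", "rarely", "sometimes", "mostly", "somewhat", "usually", "always", "never", "maybe", "perhaps"],
    "conjunctions": ["and", "but", "or", "because", "so", "while", "although", "whereas"],
    "negations": ["no", "not", "never", "none", "nothing", "cannot", "cant", "dont", "wont", "neither"],
    "verbs": ["go*", "come*", "make*", "take*", "work*", "sleep*", "eat*", "think*", "feel*", "want*", "need*", "try*", "cry*"],
    "adjectives": ["good", "bad", "happy", "sad", "tired", "calm", "nice", "great", "low", "high", "hard", "easy", "normal", "steady"],
    "comparisons": ["more", "less", "better", "worse", "best", "worst", "than", "most", "least", "higher", "lower"],
    "interrogatives": ["what", "why", "how", "when", "where", "who", "which"],
    "numbers": ["one", "two", "three", "four", "five", "ten", "first", "second", "once", "twice"],
    "quantifiers": ["all", "some", "many", "few", "lots", "much", "more", "less", "every", "enough", "moderate"],
    # --- affect ---------------------------------------------------------
    "affect": ["happy", "sad", "angry", "joy*", "love*", "hate*", "fear*", "hope*", "worr*", "anxi*", "depress*", "stress*", "upset", "proud", "content"],
    "positive emotion": ["happy", "good", "fine", "okay", "content", "hopeful", "joy*", "excited", "proud", "great", "cheerful", "peaceful", "grateful", "positive", "satisf*", "energetic", "calm", "love*", "fun", "comfortable", "nice", "relaxed", "confident", "fulfilled"],
    "negative emotion": ["sad", "depress*", "hopeless", "miserable", "gloomy", "unhappy", "angry", "anger", "hate*", "fear*", "scared", "worr*", "anxi*", "upset", "frustrat*", "irritat*", "irritable", "bad", "hurt*", "lonely", "empty", "helpless", "negative", "blue", "down"],
    "anxiety": ["anxi*", "worr*", "nervous", "afraid", "fear*", "scared", "panic*", "tense", "uneasy", "dread*", "jittery", "apprehensive", "overwhelm*", "restless", "frightened"],
    "anger": ["anger", "angry", "mad", "hate*", "furious", "rage*", "annoy*", "irritat*", "frustrat*", "hostile"],
    "sadness": ["sad", "cry*", "grief", "griev*", "depress*", "hopeless", "miserable", "gloomy", "unhappy", "blue", "down", "loss", "lonely", "empty"],
    # --- social ---------------------------------------------------------
    "social": ["friend*", "family", "people", "talk*", "social", "together", "partner", "parent*", "child*", "relationship*", "love*", "marriage", "husband", "wife"],
    "family": ["family", "mother", "father", "mom", "dad", "parent*", "child*", "children", "kids", "brother", "sister", "husband", "wife", "son", "daughter"],
    "friends": ["friend*", "buddy", "buddies", "pal", "pals", "neighbor*", "coworker*", "companion*"],
    # --- cognitive processes -------------------------------------------
    "cognitive processes": ["think*", "know*", "consider*", "because", "reason*", "understand*", "wonder*", "realiz*", "believ*", "idea*", "decide*", "maybe", "perhaps", "should", "insight*", "aware*"],
    "insight": ["think*", "know*", "understand*", "realiz*", "aware*", "insight*", "learn*", "reflect*", "recognize*", "sense", "clarity", "perspective"],
    "causation": ["because", "cause*", "effect*", "reason*", "since", "therefore", "hence", "why", "due", "result*", "make*"],
    "discrepancy": ["should", "would", "could", "wish*", "want*", "hope*", "need*", "ought", "ideally", "rather", "lacking"],
    "tentative": ["maybe", "perhaps", "guess*", "seem*", "somewhat", "fairly", "possibl*", "uncertain*", "unsure", "might", "sort", "kind"],
    "certainty": ["always", "never", "definitely", "certain*", "sure", "absolutely", "completely", "totally", "every", "all"],
    "differentiation": ["but", "not", "or", "other*", "differen*", "else", "although", "whereas", "except", "versus"],
    # --- perceptual -----------------------------------------------------
    "perception": ["see*", "look*", "hear*", "listen*", "feel*", "touch*", "taste*", "smell*", "sense*", "watch*"],
    "seeing": ["see*", "look*", "watch*", "view*", "sight", "seen", "visual*"],
    "hearing": ["hear*", "listen*", "sound*", "noise*", "loud", "quiet"],
    "feeling": ["feel*", "felt", "touch*", "numb", "warm", "cold", "soft", "hard", "aching", "pain*"],
    # --- biological -----------------------------------------------------
    "biological processes": ["body", "sleep*", "eat*", "pain*", "sick*", "health*", "tired", "blood", "head*", "stomach", "heart", "ill*"],
    "body": ["body", "head*", "hand*", "heart", "stomach", "skin", "arm*", "leg*", "face", "brain", "muscle*", "bones"],
    "health": ["health*", "sick*", "ill*", "pain*", "doctor*", "medicine*", "medicat*", "insomnia", "fatigue*", "exhaust*", "headache*", "therapy", "symptom*", "disease*", "aching"],
    "sexual": ["sex*", "intimacy", "intimate", "romantic", "passion*", "desire*"],
    "ingestion": ["eat*", "food*", "hungry", "hunger", "appetite", "meal*", "drink*", "snack*", "diet*"],
    # --- drives ---------------------------------------------------------
    "drives": ["friend*", "family", "achieve*", "success*", "win*", "power*", "control*", "risk*", "reward*", "goal*", "ambition*"],
    "affiliation": ["friend*", "family", "together", "partner", "social", "belong*", "connect*", "community", "ally", "team"],
    "achievement": ["achieve*", "success*", "accomplish*", "win*", "productive", "effort*", "goal*", "improve*", "motivat*", "unmotivated", "proud", "fail*"],
    "power": ["power*", "control*", "strong*", "weak*", "boss", "lead*", "authority", "influence*", "dominant"],
    "reward": ["reward*", "benefit*", "gain*", "prize*", "bonus", "success*", "win*", "opportunit*"],
    "risk": ["risk*", "danger*", "unsafe", "threat*", "avoid*", "caution*", "lose", "losing", "loss", "problem*"],
    # --- relativity -----------------------------------------------------
    "relativity": ["in", "on", "at", "up", "down", "near", "far", "time", "day*", "night*", "move*", "go*", "here", "there", "now", "soon"],
    "motion": ["move*", "go*", "went", "walk*", "run*", "drive*", "travel*", "arrive*", "leave*", "leaving"],
    "space": ["in", "on", "at", "up", "down", "near", "far", "here", "there", "inside", "outside", "above", "below", "around", "place*"],
    "time": ["time", "day*", "night*", "week*", "month*", "year*", "now", "soon", "today", "yesterday", "tomorrow", "morning", "evening", "hour*", "often", "always", "never", "sometimes"],
    # --- personal concerns ----------------------------------------------
    "work": ["work*", "job*", "school", "career*", "boss", "office", "college", "class*", "homework", "coworker*", "unemploy*", "study*", "studying", "deadline*", "overworked", "busy"],
    "leisure": ["fun", "play*", "game*", "hobby", "hobbies", "movie*", "music", "read*", "relax*", "vacation*", "sport*", "travel*"],
    "home": ["home", "house*", "apartment*", "room*", "kitchen", "bed*", "garden*", "chore*", "family"],
    "money": ["money", "cash", "debt*", "rent", "expense*", "income*", "saving*", "budget*", "salary", "broke", "poverty", "poor", "payment*", "bill*", "financ*", "afford*", "cost*"],
    "religion": ["god*", "pray*", "church*", "faith*", "spirit*", "bless*", "holy", "religio*"],
    "death": ["death*", "dead", "die*", "dying", "grief", "griev*", "funeral*", "mourn*", "suicid*"],
    "assent": ["yes", "yeah", "okay", "ok", "agree*", "sure", "fine", "alright", "definitely"],
}

assert len(SUBSTITUTE_LEXICON) == 63, len(SUBSTITUTE_LEXICON)
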