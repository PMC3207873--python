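{
  "education_afib": "Today we are going to be talking about atrial fibrillation, which I will be referring to as AFib. Afib is a heart problem. It's not the same heart problem that gives you a heart attack. Even though Afib is a heart problem it can cause a stroke. People generally think that heart diseases only cause problems in the chest.",
  "education_heart_brain": "People generally think that heart diseases only cause problems in the chest. But this picture shows you why atrial fibrillation can cause a stroke. As you can see the heart is connected to the brain by a big blood vessel. Afib can cause blood clots in the heart. These clots can travel up the blood vessel to the brain and cut off the blood supply to a part of the brain. This causes a stroke.",
  "sequelae_stroke": "When people hear the word stroke, they might imagine someone who can't walk or who is in a nursing home. This isn't always the case. We can't know in advance how bad a stroke will be, but in general we know that about half of all people who have a stroke will recover, one-quarter will be disabled, and one-quarter will die.",
  "sequelae_bleed": "There are 2 types of major bleeding. These can happen inside your stomach or your brain. Patients with major bleeding need to be hospitalized and have blood transfusions. We can't know in advance how bad a bleed will be, but in general we know that about three-quarters of all people who have a bleed will recover, and a small number will be disabled or die.",
  "no_perfect_medication": "So as you can see, there is no perfect medication for atrial fibrillation. Because there is no perfect medication, there is no single best choice for everyone. Each person will have different opinions about the right balance between a medication's good effects and a medication's bad effects. You need to think about how important it is to you to lower your risk of a stroke compared to the risk of having a major bleed and the hassle of taking coumadin.",
  "talk_to_doctor": "It is important for your doctor to know how you feel about these treatments. It will be important for you to talk with your doctor about your concerns, questions, and opinions. Your doctor wants and needs to know your thoughts about this, so that he/she can make the best possible recommendation for you.",
  "talking_helps": "Talking about what's important to you will help your doctor make better treatment recommendations for you.",
  "communication_opening": "How well you and your doctor talk to each other is one of the most important parts of getting good health care. But sometimes talking to your doctor is not easy because you're not sure what to say.",
  "think_one_at_a_time": "Let's think about them one at a time. What are your feelings about aspirin? What do you like about that as a treatment and what do you dislike?",
  "worksheet_prompt": "Let's think about what questions or comments you might have for your doctor. I'd like you to write them down here.",
  "physician_prompt": "I know you just learned about your treatment options for your Afib. Can you tell me how you feel about them?"
}
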